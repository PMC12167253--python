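"""Tiny enumerable MDPs and exact soft-RL oracles used to validate the
sample-based learners (kept independent of the implementation under test)."""

import numpy as np

# ---------------------------------------------------------------------------
# 5x5 gridworld: actions 0:up 1:down 2:left 3:right, state = y*5 + x
# ---------------------------------------------------------------------------

GRID_N = 5
GOAL = GRID_N * GRID_N - 1


def grid_next(s: int, a: int) -> int:
    y, x = divmod(s, GRID_N)
    if a == 0:
        y = min(y + 1, GRID_N - 1)
    elif a == 1:
        y = max(y - 1, 0)
    elif a == 2:
        x = max(x - 1, 0)
    else:
        x = min(x + 1, GRID_N - 1)
    return y * GRID_N + x


def expert_actions(s: int) -> list[int]:
    """All shortest-path actions toward the goal corner."""
    y, x = divmod(s, GRID_N)
    acts = []
    if y < GRID_N - 1:
        acts.append(0)
    if x < GRID_N - 1:
        acts.append(3)
    return acts or [0]


def expert_demos(rng: np.random.Generator) -> list[np.ndarray]:
    """One shortest-path trajectory (one-hot state features) per start state."""
    demos = []
    for s0 in range(GRID_N * GRID_N):
        s, traj = s0, [s0]
        while s != GOAL:
            s = grid_next(s, int(rng.choice(expert_actions(s))))
            traj.append(s)
        demos.append(np.eye(GRID_N * GRID_N)[traj])
    return demos


def random_trajectory_sampler(batch: int = 32, max_len: int = 10):
    def sampler(rng: np.random.Generator) -> list[np.ndarray]:
        out = []
        for _ in range(batch):
            s = int(rng.integers(GRID_N * GRID_N))
            traj = [s]
            for _ in range(int(rng.integers(1, max_len))):
                s = grid_next(s, int(rng.integers(4)))
                traj.append(s)
            out.append(np.eye(GRID_N * GRID_N)[traj])
        return out
    return sampler


def soft_value_iteration(reward_per_state: np.ndarray, gamma: float = 0.9,
                         temperature: float = 0.1, iters: int = 300) -> np.ndarray:
    """Exact soft Q for reward-on-entering; returns (n_states, 4)."""
    n = GRID_N * GRID_N
    V = np.zeros(n)
    Q = np.zeros((n, 4))
    for _ in range(iters):
        for s in range(n):
            for a in range(4):
                s2 = grid_next(s, a)
                Q[s, a] = reward_per_state[s2] + gamma * V[s2]
        V = temperature * np.logaddexp.reduce(Q / temperature, axis=1)
    return Q


# ---------------------------------------------------------------------------
# 2-state MDP with one relevant continuous action dimension (sign of a0)
# ---------------------------------------------------------------------------

TWO_STATE_REWARD = {(0, 1): 0.1, (0, -1): -0.1, (1, 1): 0.05, (1, -1): 0.0}
TWO_STATE_NEXT = {(0, 1): 1, (0, -1): 0, (1, 1): 1, (1, -1): 0}


def two_state_exact_soft_q(gamma: float, alpha: float, act_dim: int = 4,
                           iters: int = 500) -> dict:
    """Soft value iteration over the continuous action box [-1, 1]^act_dim.

    Q depends on the action only through sign(a0), so the partition integral
    over the box factorizes: irrelevant dimensions contribute volume 2 each and
    the a0 axis contributes length 1 per sign."""
    vol_irrelevant = 2.0 ** (act_dim - 1)
    V = np.zeros(2)
    for _ in range(iters):
        Q = {k: TWO_STATE_REWARD[k] + gamma * V[TWO_STATE_NEXT[k]]
             for k in TWO_STATE_REWARD}
        V = np.array([
            alpha * np.log(vol_irrelevant * (np.exp(Q[(s, 1)] / alpha)
                                             + np.exp(Q[(s, -1)] / alpha)))
            for s in (0, 1)])
    return Q
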