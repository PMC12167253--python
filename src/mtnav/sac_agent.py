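"""Recurrent Soft Actor-Critic controller for dual-device navigation.

The policy encodes the observation (optionally through an LSTM layer for
trajectory-dependent state, which lets the agent probe a branch and remember
the outcome) and a Gaussian head emits mean and standard deviation per action
dimension; actions are tanh-squashed to [-1, 1]^4. Twin soft Q-networks are
regressed toward the entropy-regularized Bellman target with Polyak-averaged
target copies, and the entropy temperature is auto-tuned toward a target
entropy. Training samples stochastically; evaluation uses the squashed mean
deterministically.

Replay stores whole episodes; recurrent updates draw fixed-length chunks that
never span episode boundaries, with a short zero-state burn-in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .evaluation import EpisodeResult, RunSummary, run_policy_episode, summarize
from .maxent_irl import observation_features
from .navigation_env import EnvConfig, NavigationEnv, Observation
from .nn import Adam, LSTMCell, MLP, Module, Tensor, concat
from .rewards import RewardConfig, RewardContext, SideModels, get_reward_fn
from .vasculature import CenterlineTree, augment_scale, target_by_index

ACT_DIM = 4
LOG_STD_MIN, LOG_STD_MAX = -5.0, 2.0


@dataclass(frozen=True)
class SacConfig:
    """SAC hyperparameters. Evaluation cadence defaults are the documented
    full-scale settings (evaluate every 2.5e5 steps for 80 episodes over 1e7
    exploration steps); desk-scale runs shrink ``total_steps``, ``eval_every``
    and the network widths."""

    discount: float = 0.99
    tau: float = 0.005
    lr: float = 1e-3
    lr_alpha: float = 1e-3
    init_alpha: float = 0.2
    auto_alpha: bool = True
    target_entropy: float = -float(ACT_DIM)
    hidden: int = 32
    use_lstm: bool = False
    lstm_hidden: int = 32
    batch_size: int = 64
    chunk_length: int = 8
    burn_in: int = 2
    replay_capacity: int = 200_000
    warmup_steps: int = 500
    update_every: int = 2
    updates_per_step: int = 1
    total_steps: int = 10_000_000
    eval_every: int = 250_000
    eval_episodes: int = 80
    augment: bool = False
    target_protocol: str = "all10"   # or "split5": train on even, eval on odd indices
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.discount < 1.0:
            raise ValueError("discount must be in (0, 1)")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must be in (0, 1]")


class PolicyNet(Module):
    """Observation encoder (optional LSTM) + Gaussian head with tanh squash."""

    def __init__(self, obs_dim: int, cfg: SacConfig, rng: np.random.Generator):
        self.use_lstm = cfg.use_lstm
        if cfg.use_lstm:
            self.lstm = LSTMCell(obs_dim, cfg.lstm_hidden, rng)
            head_in = cfg.lstm_hidden
        else:
            head_in = obs_dim
        self.head = MLP([head_in, cfg.hidden, cfg.hidden, 2 * ACT_DIM], rng)

    def init_state(self, batch: int = 1):
        return self.lstm.init_state(batch) if self.use_lstm else None

    def forward(self, obs: Tensor, state=None):
        if self.use_lstm:
            if state is None:
                state = self.lstm.init_state(obs.shape[0])
            h, state = self.lstm(obs, state)
        else:
            h = obs
        out = self.head(h)
        mu = out[:, :ACT_DIM]
        log_std = out[:, ACT_DIM:].clip(LOG_STD_MIN, LOG_STD_MAX)
        return mu, log_std, state

    def sample(self, obs: Tensor, state=None, noise: np.ndarray | None = None):
        """Reparameterized squashed-Gaussian sample with its log-probability."""
        mu, log_std, state = self.forward(obs, state)
        std = log_std.exp()
        eps = Tensor(noise if noise is not None
                     else np.random.standard_normal(mu.shape))
        u = mu + std * eps
        a = u.tanh()
        # log N(u; mu, std) - log |da/du|
        logp = (log_std + 0.5 * ((u - mu) / std) ** 2.0
                + 0.5 * np.log(2.0 * np.pi)) * -1.0
        logp = logp - (1.0 - a * a + 1e-6).log()
        return a, logp.sum(axis=-1, keepdims=True), state


class QNet(Module):
    def __init__(self, obs_dim: int, cfg: SacConfig, rng: np.random.Generator):
        self.net = MLP([obs_dim + ACT_DIM, cfg.hidden, cfg.hidden, 1], rng)

    def __call__(self, obs: Tensor, act: Tensor) -> Tensor:
        return self.net(concat([obs, act], axis=-1))


class ReplayBuffer:
    """Episode-structured FIFO replay. Chunk sampling never crosses episodes."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self.episodes: list[dict] = []
        self.size = 0
        self._current: dict | None = None

    def start_episode(self) -> None:
        self._current = {"obs": [], "act": [], "rew": [], "done": [], "next_obs": []}

    def add(self, obs, act, rew, done, next_obs) -> None:
        c = self._current
        c["obs"].append(obs)
        c["act"].append(act)
        c["rew"].append(rew)
        c["done"].append(done)
        c["next_obs"].append(next_obs)

    def end_episode(self) -> None:
        if self._current and self._current["obs"]:
            ep = {k: np.asarray(v, dtype=np.float64) for k, v in self._current.items()}
            self.episodes.append(ep)
            self.size += len(ep["rew"])
            while self.size > self.capacity and len(self.episodes) > 1:
                self.size -= len(self.episodes.pop(0)["rew"])
        self._current = None

    def sample_transitions(self, batch: int, rng: np.random.Generator):
        lens = np.array([len(e["rew"]) for e in self.episodes])
        probs = lens / lens.sum()
        eidx = rng.choice(len(self.episodes), size=batch, p=probs)
        out = {k: [] for k in ("obs", "act", "rew", "done", "next_obs")}
        for ei in eidx:
            ep = self.episodes[ei]
            t = int(rng.integers(len(ep["rew"])))
            for k in out:
                out[k].append(ep[k][t])
        return {k: np.asarray(v) for k, v in out.items()}

    def sample_chunks(self, batch: int, length: int, rng: np.random.Generator):
        """(batch, length, ...) arrays; short episodes are front-padded by
        repeating their first transition (masked out via ``valid``)."""
        chunks = {k: [] for k in ("obs", "act", "rew", "done", "next_obs")}
        valid = []
        lens = np.array([len(e["rew"]) for e in self.episodes])
        probs = lens / lens.sum()
        for ei in rng.choice(len(self.episodes), size=batch, p=probs):
            ep = self.episodes[ei]
            T = len(ep["rew"])
            if T >= length:
                t0 = int(rng.integers(T - length + 1))
                sl = slice(t0, t0 + length)
                for k in chunks:
                    chunks[k].append(ep[k][sl])
                valid.append(np.ones(length))
            else:
                pad = length - T
                for k in chunks:
                    arr = ep[k]
                    chunks[k].append(np.concatenate([np.repeat(arr[:1], pad, axis=0), arr]))
                valid.append(np.concatenate([np.zeros(pad), np.ones(T)]))
        return ({k: np.asarray(v) for k, v in chunks.items()}, np.asarray(valid))


@dataclass
class TrainResult:
    eval_log: list[dict]
    best_success_rate: float
    best_weights: list
    final_weights: list
    agent: "SacAgent"
    exploration_force_mean: float = 0.0   # mean ||P|| over all exploration steps
    exploration_force_exceedance: float = 0.0  # fraction of steps above threshold


class SacAgent:
    """SAC learner over feature vectors (see ``observation_features``)."""

    def __init__(self, obs_dim: int, cfg: SacConfig):
        self.cfg = cfg
        self.obs_dim = obs_dim
        rng = np.random.default_rng(cfg.seed)
        self.policy = PolicyNet(obs_dim, cfg, rng)
        self.q1 = QNet(obs_dim, cfg, rng)
        self.q2 = QNet(obs_dim, cfg, rng)
        self.q1_target = QNet(obs_dim, cfg, rng)
        self.q2_target = QNet(obs_dim, cfg, rng)
        self.q1_target.copy_from(self.q1)
        self.q2_target.copy_from(self.q2)
        self.opt_policy = Adam(self.policy.parameters(), lr=cfg.lr)
        self.opt_q = Adam(self.q1.parameters() + self.q2.parameters(), lr=cfg.lr)
        self.log_alpha = float(np.log(cfg.init_alpha))
        self._act_rng = np.random.default_rng(cfg.seed + 1)

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha))

    # -- acting --------------------------------------------------------------
    def act(self, features: np.ndarray, recurrent_state=None,
            mode: str = "stochastic"):
        f = np.asarray(features, dtype=np.float64)
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite observation features")
        obs = Tensor(f.reshape(1, -1))
        if mode == "deterministic":
            mu, _, state = self.policy.forward(obs, recurrent_state)
            return np.tanh(mu.data.ravel()), state
        noise = self._act_rng.standard_normal((1, ACT_DIM))
        a, _, state = self.policy.sample(obs, recurrent_state, noise=noise)
        return a.data.ravel().copy(), state

    def policy_fn(self, mode: str = "deterministic") -> Callable[[Observation], np.ndarray]:
        """A stateful per-episode policy callable over raw Observations."""
        state = {"rec": self.policy.init_state(1)}

        def policy(obs: Observation) -> np.ndarray:
            a, state["rec"] = self.act(observation_features(obs), state["rec"], mode)
            return a

        return policy

    # -- updates -------------------------------------------------------------
    def _soft_target(self, next_obs: Tensor, rew: np.ndarray, done: np.ndarray,
                     noise: np.ndarray, next_state=None) -> np.ndarray:
        a2, logp2, _ = self.policy.sample(next_obs, next_state, noise=noise)
        q1t = self.q1_target(next_obs, a2).data
        q2t = self.q2_target(next_obs, a2).data
        qmin = np.minimum(q1t, q2t) - self.alpha * logp2.data
        return rew.reshape(-1, 1) + self.cfg.discount * (1.0 - done.reshape(-1, 1)) * qmin

    def update(self, batch: dict, rng: np.random.Generator) -> dict:
        """One SAC update from a flat transition batch."""
        cfg = self.cfg
        obs = Tensor(batch["obs"])
        act = Tensor(batch["act"])
        B = obs.shape[0]

        y = self._soft_target(Tensor(batch["next_obs"]), batch["rew"], batch["done"],
                              noise=rng.standard_normal((B, ACT_DIM)))

        q1 = self.q1(obs, act)
        q2 = self.q2(obs, act)
        yt = Tensor(y)
        q_loss = ((q1 - yt) ** 2.0).mean() + ((q2 - yt) ** 2.0).mean()
        self.opt_q.zero_grad()
        self.opt_policy.zero_grad()
        q_loss.backward()
        self.opt_q.step()

        a_new, logp, _ = self.policy.sample(obs, noise=rng.standard_normal((B, ACT_DIM)))
        q_new = self.q1(obs, a_new)
        q_new2 = self.q2(obs, a_new)
        sel = Tensor((q_new.data <= q_new2.data).astype(float))
        q_min = q_new * sel + q_new2 * (1.0 - sel)   # elementwise min of the twins
        pi_loss = (self.alpha * logp - q_min).mean()
        self.opt_policy.zero_grad()
        self.opt_q.zero_grad()
        pi_loss.backward()
        self.opt_policy.step()

        mean_logp = float(logp.data.mean())
        if cfg.auto_alpha:
            self.log_alpha += cfg.lr_alpha * (mean_logp + cfg.target_entropy)

        self.q1_target.copy_from(self.q1, cfg.tau)
        self.q2_target.copy_from(self.q2, cfg.tau)
        return {"q_loss": float(q_loss.data), "pi_loss": float(pi_loss.data),
                "alpha": self.alpha, "entropy": -mean_logp}

    def update_recurrent(self, chunks: dict, valid: np.ndarray,
                         rng: np.random.Generator) -> dict:
        """SAC update over (batch, length, ...) sequence chunks with burn-in."""
        cfg = self.cfg
        B, L, D = chunks["obs"].shape
        mask = valid.copy()
        mask[:, :cfg.burn_in] = 0.0
        w = mask / max(mask.sum(), 1.0)

        # run the policy over obs_0..obs_{L-1}, next_obs_{L-1}
        seq = np.concatenate([chunks["obs"], chunks["next_obs"][:, -1:, :]], axis=1)
        noises = rng.standard_normal((L + 1, B, ACT_DIM))
        state = self.policy.init_state(B)
        samples = []
        for t in range(L + 1):
            a, logp, state = self.policy.sample(Tensor(seq[:, t, :]), state,
                                                noise=noises[t])
            samples.append((a, logp))

        # critic targets: policy sample at t+1 on the target critics
        q_losses = []
        ys = np.zeros((B, L, 1))
        for t in range(L):
            a2, logp2 = samples[t + 1]
            no = Tensor(seq[:, t + 1, :])
            qmin = np.minimum(self.q1_target(no, a2.detach()).data,
                              self.q2_target(no, a2.detach()).data) \
                - self.alpha * logp2.data
            ys[:, t] = (chunks["rew"][:, t].reshape(-1, 1)
                        + cfg.discount * (1.0 - chunks["done"][:, t].reshape(-1, 1)) * qmin)
        obs_flat = Tensor(chunks["obs"].reshape(B * L, D))
        act_flat = Tensor(chunks["act"].reshape(B * L, ACT_DIM))
        y_flat = Tensor(ys.reshape(B * L, 1))
        w_flat = Tensor(w.reshape(B * L, 1))
        q1 = self.q1(obs_flat, act_flat)
        q2 = self.q2(obs_flat, act_flat)
        q_loss = (((q1 - y_flat) ** 2.0) * w_flat).sum() + (((q2 - y_flat) ** 2.0) * w_flat).sum()
        self.opt_q.zero_grad()
        self.opt_policy.zero_grad()
        q_loss.backward()
        self.opt_q.step()
        q_losses.append(float(q_loss.data))

        # policy loss over the chunk (BPTT through the LSTM)
        pi_terms = None
        logp_acc = 0.0
        for t in range(cfg.burn_in, L):
            a, logp = samples[t]
            o = Tensor(chunks["obs"][:, t, :])
            q = self.q1(o, a)
            term = ((self.alpha * logp - q) * Tensor(w[:, t:t + 1])).sum()
            pi_terms = term if pi_terms is None else pi_terms + term
            logp_acc += float((logp.data * w[:, t:t + 1]).sum())
        self.opt_policy.zero_grad()
        self.opt_q.zero_grad()
        pi_terms.backward()
        self.opt_policy.step()

        if cfg.auto_alpha:
            self.log_alpha += cfg.lr_alpha * (logp_acc + cfg.target_entropy)
        self.q1_target.copy_from(self.q1, cfg.tau)
        self.q2_target.copy_from(self.q2, cfg.tau)
        return {"q_loss": q_losses[-1], "pi_loss": float(pi_terms.data),
                "alpha": self.alpha}

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path, meta: dict | None = None) -> None:
        from dataclasses import asdict
        payload = {
            "meta": {"obs_dim": self.obs_dim, "log_alpha": self.log_alpha,
                     **(meta or {})},
            "config": asdict(self.cfg),
            "policy": self.policy.state_list(),
            "q1": self.q1.state_list(),
            "q2": self.q2.state_list(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SacAgent":
        payload = json.loads(Path(path).read_text())
        cfgd = payload["config"]
        cfgd["hidden"] = int(cfgd["hidden"])
        cfg = SacConfig(**cfgd)
        agent = cls(payload["meta"]["obs_dim"], cfg)
        agent.policy.load_state_list(payload["policy"])
        agent.q1.load_state_list(payload["q1"])
        agent.q2.load_state_list(payload["q2"])
        agent.q1_target.copy_from(agent.q1)
        agent.q2_target.copy_from(agent.q2)
        agent.log_alpha = payload["meta"]["log_alpha"]
        return agent


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _protocol_indices(protocol: str) -> tuple[list[int], list[int]]:
    if protocol == "split5":
        return [0, 2, 4, 6, 8], [1, 3, 5, 7, 9]
    return list(range(10)), list(range(10))


def evaluate_policy(agent: SacAgent, trees: Sequence[CenterlineTree],
                    target_indices: Sequence[int], episodes: int,
                    env_config: EnvConfig | None = None, seed: int = 0,
                    ) -> tuple[RunSummary, list[EpisodeResult]]:
    """Deterministic evaluation across (tree, target) combinations."""
    combos = [(tr, ti) for tr in trees for ti in target_indices]
    results = []
    env = NavigationEnv(env_config)
    for k in range(episodes):
        tree, ti = combos[k % len(combos)]
        target = target_by_index(tree, ti)
        results.append(run_policy_episode(
            agent.policy_fn("deterministic"), tree, target,
            seed=seed + k, env=env))
    return summarize(results), results


def train_rl(train_trees: Sequence[CenterlineTree], cfg: SacConfig,
             reward_name: str = "R1", reward_cfg: RewardConfig | None = None,
             irl_models: SideModels | None = None,
             env_config: EnvConfig | None = None,
             eval_trees: Sequence[CenterlineTree] | None = None,
             log_path: str | Path | None = None) -> TrainResult:
    """Off-policy training: explore with stochastic actions, update from
    replay, evaluate deterministically every ``eval_every`` steps, and keep
    the checkpoint with the highest evaluation success rate."""
    reward_cfg = reward_cfg or RewardConfig()
    reward_fn = get_reward_fn(reward_name, reward_cfg, irl_models)
    env = NavigationEnv(env_config)
    obs_dim = Observation.vector_size()
    agent = SacAgent(obs_dim, cfg)
    buffer = ReplayBuffer(cfg.replay_capacity)
    rng = np.random.default_rng(cfg.seed)
    train_idx, eval_idx = _protocol_indices(cfg.target_protocol)
    eval_trees = list(eval_trees) if eval_trees is not None else list(train_trees)

    eval_log: list[dict] = []
    best_rate, best_weights = -1.0, agent.policy.state_list()
    steps = 0
    force_sum = 0.0
    force_exceed = 0
    while steps < cfg.total_steps:
        tree = train_trees[int(rng.integers(len(train_trees)))]
        if cfg.augment:
            tree = augment_scale(tree, float(rng.uniform(0.7, 1.3)),
                                 float(rng.uniform(0.7, 1.3)))
        target = target_by_index(tree, train_idx[int(rng.integers(len(train_idx)))])
        obs = env.reset(tree, target, seed=int(rng.integers(2**31 - 1)))
        feats = observation_features(obs)
        rec_state = agent.policy.init_state(1)
        buffer.start_episode()
        while not env.done and steps < cfg.total_steps:
            if steps < cfg.warmup_steps:
                action = rng.uniform(-1.0, 1.0, ACT_DIM)
                _, rec_state = agent.act(feats, rec_state, "deterministic") \
                    if cfg.use_lstm else (None, rec_state)
            else:
                action, rec_state = agent.act(feats, rec_state, "stochastic")
            res = env.step(action)
            ctx = RewardContext(
                delta_pathlength=res.info["delta_pathlength"],
                reached=res.reached,
                force_magnitude=float(np.linalg.norm(res.tip_force)),
                observation=res.observation,
                target_side=tree.side)
            r = reward_fn(ctx)
            force_sum += ctx.force_magnitude
            force_exceed += ctx.force_magnitude > reward_cfg.force_threshold
            next_feats = observation_features(res.observation)
            buffer.add(feats, action, r, float(res.reached), next_feats)
            feats = next_feats
            steps += 1

            if (steps >= cfg.warmup_steps and steps % cfg.update_every == 0
                    and buffer.size >= cfg.batch_size):
                for _ in range(cfg.updates_per_step):
                    if cfg.use_lstm:
                        chunks, valid = buffer.sample_chunks(
                            max(cfg.batch_size // cfg.chunk_length, 4),
                            cfg.chunk_length, rng)
                        agent.update_recurrent(chunks, valid, rng)
                    else:
                        agent.update(buffer.sample_transitions(cfg.batch_size, rng), rng)

            if steps % cfg.eval_every == 0:
                summary, _ = evaluate_policy(
                    agent, eval_trees, eval_idx, cfg.eval_episodes,
                    env_config, seed=cfg.seed + steps)
                record = {"step": steps, "success_rate": summary.success_rate,
                          "procedure_time": summary.procedure_time_mean,
                          "path_ratio": summary.path_ratio_mean,
                          "mean_force": summary.mean_force_mean,
                          "alpha": agent.alpha}
                eval_log.append(record)
                if summary.success_rate > best_rate:
                    best_rate = summary.success_rate
                    best_weights = agent.policy.state_list()
        buffer.end_episode()

    if log_path is not None:
        import csv
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=[
                "step", "success_rate", "procedure_time", "path_ratio",
                "mean_force", "alpha"])
            writer.writeheader()
            writer.writerows(eval_log)
    return TrainResult(eval_log=eval_log, best_success_rate=best_rate,
                       best_weights=best_weights,
                       final_weights=agent.policy.state_list(), agent=agent,
                       exploration_force_mean=force_sum / max(steps, 1),
                       exploration_force_exceedance=force_exceed / max(steps, 1))
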