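"""Maximum-entropy inverse reinforcement learning from demonstrations.

A feedforward reward network (four fully connected layers) scores single
observations. Trajectories are scored as the sum of per-step rewards minus a
per-step length penalty; under the maximum-entropy model a trajectory's
probability is proportional to exp(score / alpha), where alpha is the entropy
regularization weight. Training ascends the demonstration likelihood with the
partition term estimated from sampled background trajectories (guided-cost
style): the loss is

    L = alpha * logsumexp(score_background / alpha) - mean(score_demo)

whose gradient is the background-softmax feature expectation minus the
demonstration feature expectation.

Separate models are trained per vascular side (right/left carotid approach),
and the ipsilateral model supplies R2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .demonstrations import Demonstration, demo_observations, split_by_side
from .navigation_env import Observation
from .nn import Adam, MLP, Tensor

# coordinates are mm at ~100 mm scene scale; actions are already in [-1, 1]
_COORD_SCALE = 0.01


class DataError(ValueError):
    """Demonstration set unusable for IRL training."""


class TrainingError(RuntimeError):
    """Loss became non-finite during IRL training."""


@dataclass(frozen=True)
class IrlTrainConfig:
    """Defaults are the documented full-scale settings; desk-scale runs lower
    ``iterations`` (the loss landscape at this problem size converges within a
    few hundred steps)."""

    iterations: int = 1_000_000
    learning_rate: float = 1e-2
    entropy_reg: float = 0.1       # alpha: temperature of the max-ent model
    length_penalty: float = 0.01   # per-step score penalty
    hidden: tuple[int, ...] = (32, 32, 32)
    background_batch: int = 32
    seed: int = 0


def observation_features(obs: Observation) -> np.ndarray:
    """Feature vector for the reward net: the agent's own observation vector,
    with coordinates rescaled to O(1)."""
    v = obs.as_vector().copy()
    v[:26] *= _COORD_SCALE  # tracked points + target (positions in mm)
    return v


class IrlRewardModel:
    """Four-layer fully connected reward network over observation features."""

    def __init__(self, n_in: int, hidden: Sequence[int] = (32, 32, 32),
                 side: str = "unsided", seed: int = 0):
        if len(hidden) != 3:
            raise ValueError("exactly 4 fully connected layers: 3 hidden sizes + output")
        rng = np.random.default_rng(seed)
        self.n_in = n_in
        self.hidden = tuple(hidden)
        self.side = side
        self.net = MLP([n_in, *hidden, 1], rng)

    def forward(self, features: Tensor) -> Tensor:
        return self.net(features)

    def score(self, features: np.ndarray) -> float:
        """Scalar reward for one feature vector (pure function)."""
        f = np.asarray(features, float)
        if f.shape[-1] != self.n_in:
            raise ValueError(f"expected {self.n_in} features, got {f.shape[-1]}")
        out = self.net(Tensor(f.reshape(1, -1)))
        return float(out.data.ravel()[0])

    def score_batch(self, features: np.ndarray) -> np.ndarray:
        return self.net(Tensor(np.atleast_2d(features))).data.ravel()

    # -- persistence (text checkpoint) ---------------------------------------
    def save(self, path: str | Path, extra_meta: dict | None = None) -> None:
        payload = {
            "meta": {"n_in": self.n_in, "hidden": list(self.hidden),
                     "side": self.side, **(extra_meta or {})},
            "weights": self.net.state_list(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "IrlRewardModel":
        payload = json.loads(Path(path).read_text())
        meta = payload["meta"]
        model = cls(meta["n_in"], meta["hidden"], meta["side"])
        model.net.load_state_list(payload["weights"])
        return model


def irl_reward(model: IrlRewardModel, observation: Observation) -> float:
    """Evaluate the IRL reward on a single observation."""
    return model.score(observation_features(observation))


def _trajectory_score(model: IrlRewardModel, features: np.ndarray,
                      length_penalty: float) -> Tensor:
    per_step = model.forward(Tensor(features))     # (T, 1)
    return per_step.sum() - length_penalty * len(features)


def irl_objective(model: IrlRewardModel, demos: Sequence[np.ndarray],
                  background: Sequence[np.ndarray], cfg: IrlTrainConfig) -> Tensor:
    """Negative demonstration log-likelihood (up to constants) under the
    max-ent trajectory model, with the partition term estimated from the
    background set: alpha * logsumexp(score/alpha) - mean(demo scores)."""
    alpha = cfg.entropy_reg
    back_scores = [_trajectory_score(model, b, cfg.length_penalty) / alpha
                   for b in background]
    m = max(float(s.data) for s in back_scores)
    exp_sum = None
    for s in back_scores:
        e = (s - m).exp()
        exp_sum = e if exp_sum is None else exp_sum + e
    log_z = exp_sum.log() + m
    mean_demo = None
    for t in demos:
        s = _trajectory_score(model, t, cfg.length_penalty)
        mean_demo = s if mean_demo is None else mean_demo + s
    mean_demo = mean_demo * (1.0 / len(demos))
    return alpha * log_z - mean_demo


def fit_irl(demo_trajectories: Sequence[np.ndarray], cfg: IrlTrainConfig,
            sampler: Callable[[np.random.Generator], list[np.ndarray]],
            n_in: int | None = None, side: str = "unsided",
            callback: Callable[[int, float], None] | None = None) -> IrlRewardModel:
    """Fit a reward model to demonstration trajectories.

    ``demo_trajectories`` are (T, d) feature arrays; ``sampler`` returns
    background trajectories in the same feature space. Deterministic under
    ``cfg.seed`` up to floating-point accumulation order.
    """
    demos = [np.atleast_2d(np.asarray(d, float)) for d in demo_trajectories]
    if not demos:
        raise DataError("at least one demonstration trajectory is required")
    d = demos[0].shape[1] if n_in is None else n_in
    model = IrlRewardModel(d, cfg.hidden, side=side, seed=cfg.seed)
    opt = Adam(model.net.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    for it in range(cfg.iterations):
        background = sampler(rng)
        if not background:
            raise DataError("background sampler returned no trajectories")
        loss = irl_objective(model, demos, background, cfg)
        if not np.isfinite(loss.data):
            raise TrainingError(
                f"non-finite IRL loss at iteration {it}: {float(loss.data)} "
                f"(log_z={float(log_z.data)}, demo={float(mean_demo.data)})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        if callback is not None:
            callback(it, float(loss.data))
    return model


# ---------------------------------------------------------------------------
# navigation-domain wrappers
# ---------------------------------------------------------------------------

def demo_feature_trajectories(demos: Sequence[Demonstration]) -> list[np.ndarray]:
    """Feature trajectories for the successful demonstrations only."""
    out = []
    for demo in demos:
        if demo.outcome != "success":
            continue
        feats = np.stack([observation_features(o) for o in demo_observations(demo)])
        out.append(feats)
    if not out:
        raise DataError("no successful demonstrations to train on")
    return out


def make_shuffle_sampler(demo_trajs: Sequence[np.ndarray], batch: int,
                         noise: float = 0.05) -> Callable[[np.random.Generator], list[np.ndarray]]:
    """Background sampler that perturbs and time-shuffles demonstration
    features — a demo-anchored approximation of the partition term used when
    environment rollouts are too expensive. Background trajectories keep the
    source trajectory's length so the partition term tracks the demo score
    scale (a length mismatch would make the objective unbounded)."""

    def sampler(rng: np.random.Generator) -> list[np.ndarray]:
        out = []
        for _ in range(batch):
            base = demo_trajs[int(rng.integers(len(demo_trajs)))]
            idx = rng.permutation(len(base))
            out.append(base[idx] + noise * rng.standard_normal(base.shape))
        return out

    return sampler


def train_side_models(demos: Sequence[Demonstration], cfg: IrlTrainConfig,
                      sampler_factory: Callable[[list[np.ndarray]], Callable] | None = None,
                      ) -> dict[str, IrlRewardModel]:
    """Train one reward model per vascular side from a mixed demo set."""
    by_side = split_by_side(list(demos))
    models: dict[str, IrlRewardModel] = {}
    for side in ("left", "right"):
        if not by_side[side]:
            raise DataError(f"no demonstrations for side {side!r}")
        trajs = demo_feature_trajectories(by_side[side])
        factory = sampler_factory or (
            lambda t: make_shuffle_sampler(t, cfg.background_batch))
        models[side] = fit_irl(trajs, cfg, factory(trajs), side=side)
    return models


def as_side_models(models: dict[str, IrlRewardModel]):
    """Adapt trained models to the rewards module's dispatch table."""
    return {side: (lambda obs, m=model: irl_reward(m, obs))
            for side, model in models.items()}
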