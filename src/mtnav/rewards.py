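"""The six reward functions for dual-device navigation.

R1 is a dense shaping reward: a per-step penalty, a term proportional to the
change in tip-to-target pathlength, and a terminal bonus on reaching the
target. R2 dispatches to a side-specific IRL-learned reward model (right- or
left-carotid approach). R3 combines them, R3 = R1 + alpha * R2 with
alpha = 0.001. R4, R5, R6 add a guidewire tip-force penalty to R1, R2, R3:
zero at or below 0.85 N, then linear with slope 0.01 per newton.

Delta-pathlength is signed current minus previous, so progress toward the
target (negative delta) contributes positively through the -0.001 coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .navigation_env import Observation

REWARD_NAMES = ("R1", "R2", "R3", "R4", "R5", "R6")


class ConfigurationError(ValueError):
    """A required IRL side model is missing."""


@dataclass(frozen=True)
class RewardConfig:
    step_penalty: float = -0.005
    pathlength_coeff: float = -0.001   # per mm of delta-pathlength
    terminal_bonus: float = 1.0
    irl_scale: float = 0.001           # alpha in the combined model
    force_threshold: float = 0.85      # N
    force_slope: float = 0.01          # penalty per N above threshold


@dataclass
class RewardContext:
    """Per-step quantities feeding the reward functions."""

    delta_pathlength: float            # mm, current minus previous
    reached: bool
    force_magnitude: float             # N, ||P|| at the guidewire tip
    observation: Observation | None = None
    target_side: str = "right"

    def __post_init__(self):
        if self.force_magnitude < 0:
            raise ValueError("force_magnitude must be non-negative")


SideModels = dict[str, Callable[[Observation], float]]


def reward_dense(ctx: RewardContext, cfg: RewardConfig | None = None) -> float:
    """R1: step penalty + pathlength shaping + terminal bonus."""
    cfg = cfg or RewardConfig()
    if not math.isfinite(ctx.delta_pathlength):
        raise ValueError(f"non-finite delta_pathlength: {ctx.delta_pathlength}")
    r = cfg.step_penalty + cfg.pathlength_coeff * ctx.delta_pathlength
    if ctx.reached:
        r += cfg.terminal_bonus
    return r


def reward_irl(ctx: RewardContext, models: SideModels) -> float:
    """R2: the ipsilateral IRL model evaluated on the current observation."""
    if ctx.target_side not in models:
        raise ConfigurationError(
            f"no IRL reward model registered for side {ctx.target_side!r}")
    return float(models[ctx.target_side](ctx.observation))


def reward_combined(ctx: RewardContext, cfg: RewardConfig | None = None,
                    models: SideModels | None = None) -> float:
    """R3 = R1 + alpha * R2."""
    cfg = cfg or RewardConfig()
    return reward_dense(ctx, cfg) + cfg.irl_scale * reward_irl(ctx, models or {})


def force_penalty(force_magnitude: float, cfg: RewardConfig | None = None) -> float:
    """Non-positive penalty: 0 at or below the threshold, linear above it."""
    cfg = cfg or RewardConfig()
    if force_magnitude < 0:
        raise ValueError("force magnitude must be non-negative")
    if force_magnitude <= cfg.force_threshold:
        return 0.0
    return -cfg.force_slope * (force_magnitude - cfg.force_threshold)


def reward_with_force(base: Callable[..., float], ctx: RewardContext,
                      cfg: RewardConfig | None = None,
                      models: SideModels | None = None) -> float:
    """R4/R5/R6: the corresponding base reward plus the tip-force penalty."""
    cfg = cfg or RewardConfig()
    if base is reward_dense:
        b = reward_dense(ctx, cfg)
    elif base is reward_irl:
        b = reward_irl(ctx, models or {})
    else:
        b = reward_combined(ctx, cfg, models)
    return b + force_penalty(ctx.force_magnitude, cfg)


def get_reward_fn(name: str, cfg: RewardConfig | None = None,
                  models: SideModels | None = None) -> Callable[[RewardContext], float]:
    """Look up a reward function by its experiment-config name R1..R6."""
    cfg = cfg or RewardConfig()
    name = name.upper()
    if name not in REWARD_NAMES:
        raise ValueError(f"unknown reward {name!r}; expected one of {REWARD_NAMES}")
    if name in ("R2", "R3", "R5", "R6") and not models:
        raise ConfigurationError(f"reward {name} requires IRL side models")
    table = {
        "R1": lambda ctx: reward_dense(ctx, cfg),
        "R2": lambda ctx: reward_irl(ctx, models),
        "R3": lambda ctx: reward_combined(ctx, cfg, models),
        "R4": lambda ctx: reward_with_force(reward_dense, ctx, cfg),
        "R5": lambda ctx: reward_with_force(reward_irl, ctx, cfg, models),
        "R6": lambda ctx: reward_with_force(reward_combined, ctx, cfg, models),
    }
    return table[name]
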