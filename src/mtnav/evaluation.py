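"""Per-episode and per-run evaluation metrics, and comparison statistics.

Success rate is the percentage of evaluation episodes that reach the target;
procedure time is steps x dt for successful episodes only; path ratio is the
percentage of the initial tip-to-target distance covered, reported for failed
episodes (successes are 100 by definition); mean force averages the tip-force
magnitude over all steps of all episodes. Pairwise comparisons use two-tailed
paired t-tests, multi-group comparisons one-way ANOVA, at a 0.05 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .navigation_env import EnvConfig, NavigationEnv, Observation
from .vasculature import CenterlineTree, TargetSpec

SIGNIFICANCE_LEVEL = 0.05


class DataError(ValueError):
    pass


@dataclass
class EpisodeResult:
    success: bool
    steps: int
    dt: float
    initial_pathlength: float     # mm
    final_pathlength: float       # mm
    mean_force: float             # N, averaged over the episode's steps
    max_force: float              # N

    @property
    def procedure_time(self) -> float | None:
        """Seconds from start to target; defined for successful episodes only."""
        return self.steps * self.dt if self.success else None


@dataclass
class RunSummary:
    n_episodes: int
    success_rate: float                      # %
    procedure_time_mean: float | None        # s (successes only)
    procedure_time_sd: float | None
    path_ratio_mean: float | None            # % (failures only)
    path_ratio_sd: float | None
    mean_force_mean: float                   # N over all steps of all episodes
    mean_force_sd: float
    exploration_steps: int = 0


def path_ratio(episode: EpisodeResult) -> float:
    """Percentage of the initial distance covered, clipped to [0, 100]."""
    if episode.initial_pathlength <= 0:
        raise DataError("degenerate episode: initial pathlength must be > 0")
    if episode.success:
        return 100.0
    covered = episode.initial_pathlength - episode.final_pathlength
    return float(np.clip(100.0 * covered / episode.initial_pathlength, 0.0, 100.0))


def summarize(episodes: Sequence[EpisodeResult], exploration_steps: int = 0) -> RunSummary:
    if not episodes:
        raise DataError("at least one episode is required")
    n = len(episodes)
    successes = [e for e in episodes if e.success]
    failures = [e for e in episodes if not e.success]
    times = np.array([e.procedure_time for e in successes]) if successes else None
    ratios = np.array([path_ratio(e) for e in failures]) if failures else None
    forces = np.array([e.mean_force for e in episodes])
    return RunSummary(
        n_episodes=n,
        success_rate=100.0 * len(successes) / n,
        procedure_time_mean=float(times.mean()) if times is not None else None,
        procedure_time_sd=float(times.std(ddof=1)) if times is not None and len(times) > 1
        else (0.0 if times is not None else None),
        path_ratio_mean=float(ratios.mean()) if ratios is not None else None,
        path_ratio_sd=float(ratios.std(ddof=1)) if ratios is not None and len(ratios) > 1
        else (0.0 if ratios is not None else None),
        mean_force_mean=float(forces.mean()),
        mean_force_sd=float(forces.std(ddof=1)) if n > 1 else 0.0,
        exploration_steps=exploration_steps,
    )


def compare_runs(a: Sequence[float], b: Sequence[float] | None = None,
                 *groups: Sequence[float], paired: bool = True) -> dict:
    """Two-tailed paired t-test for two samples; one-way ANOVA for more."""
    if groups:
        f, p = stats.f_oneway(np.asarray(a, float), np.asarray(b, float),
                              *[np.asarray(g, float) for g in groups])
        return {"test": "anova", "statistic": float(f), "p_value": float(p),
                "significant": bool(p < SIGNIFICANCE_LEVEL)}
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        if len(a) != len(b):
            raise DataError(f"paired samples must have equal length ({len(a)} vs {len(b)})")
        if np.allclose(a, b):
            return {"test": "paired_t", "statistic": 0.0, "p_value": 1.0,
                    "significant": False}
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return {"test": "paired_t" if paired else "t", "statistic": float(t),
            "p_value": float(p), "significant": bool(p < SIGNIFICANCE_LEVEL)}


# ---------------------------------------------------------------------------
# rollout helpers
# ---------------------------------------------------------------------------

def run_policy_episode(policy: Callable[[Observation], np.ndarray],
                       tree: CenterlineTree, target: TargetSpec,
                       config: EnvConfig | None = None, seed: int = 0,
                       env: NavigationEnv | None = None) -> EpisodeResult:
    """Roll one episode under ``policy`` (a callable Observation -> action)."""
    env = env or NavigationEnv(config)
    obs = env.reset(tree, target, seed=seed)
    initial = env.pathlength
    forces = []
    reached = False
    while not env.done:
        res = env.step(policy(obs))
        obs = res.observation
        forces.append(float(np.linalg.norm(res.tip_force)))
        reached = res.reached
    return EpisodeResult(
        success=reached, steps=env.step_index, dt=env.config.dt,
        initial_pathlength=initial, final_pathlength=env.pathlength,
        mean_force=float(np.mean(forces)) if forces else 0.0,
        max_force=float(np.max(forces)) if forces else 0.0)
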