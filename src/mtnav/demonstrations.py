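"""Scripted demonstrator and demonstration storage.

A centerline-following oracle stands in for a human keyboard demonstrator: it
is privileged (it sees the vessel tree and the device state, unlike the
learning agent), translates at a speed proportional to the remaining
pathlength, and rotates the curved guidewire tip ahead of the bifurcation so
that the target branch is selected. Recorded trajectories are stored one file
per demonstration as columnar TSV with a JSON header, and split by target side
for per-branch IRL training.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .navigation_env import GUIDEWIRE, CATHETER, EnvConfig, NavigationEnv, Observation
from .vasculature import (CenterlineTree, TargetSpec, TARGET_BRANCH,
                          DISTRACTOR_BRANCH, geodesic_distance, sample_target)

SCHEMA_VERSION = 1


@dataclass
class DemoStep:
    action: np.ndarray              # (4,)
    guidewire_points: np.ndarray    # (3, 2) after the action
    catheter_points: np.ndarray     # (3, 2)
    force_magnitude: float


@dataclass
class Demonstration:
    case_id: str
    target: TargetSpec
    initial_guidewire_points: np.ndarray
    initial_catheter_points: np.ndarray
    steps: list[DemoStep]
    outcome: str                    # "success" | "timeout"

    @property
    def n_steps(self) -> int:
        return len(self.steps)


class OraclePolicy:
    """Privileged centerline-following demonstrator for one environment."""

    def __init__(self, env: NavigationEnv, lookahead: float = 25.0,
                 slow_radius: float = 12.0):
        self.env = env
        self.lookahead = lookahead
        self.slow_radius = slow_radius
        tree = env.tree
        kids = tree.children()
        bifs = [i for i, k in enumerate(kids) if len(k) > 1]
        self.bif_node = bifs[0] if bifs else None
        if self.bif_node is not None:
            # signed turn of the target branch relative to the trunk tangent
            t_first = next(k for k in kids[self.bif_node]
                           if tree.branch_label[k] == TARGET_BRANCH)
            trunk_dir = tree.nodes[self.bif_node] - tree.nodes[tree.parent[self.bif_node]]
            trunk_dir /= np.linalg.norm(trunk_dir)
            branch_dir = tree.nodes[t_first] - tree.nodes[self.bif_node]
            branch_dir /= np.linalg.norm(branch_dir)
            self.turn_deg = float(np.degrees(
                np.arctan2(trunk_dir[0] * branch_dir[1] - trunk_dir[1] * branch_dir[0],
                           trunk_dir @ branch_dir)))
        else:
            self.turn_deg = 0.0

    def _desired_rotation(self) -> float:
        """Axial rotation (deg) whose in-plane deflection matches the branch turn."""
        curve = self.env.config.tip_curve_angle
        c = np.clip(self.turn_deg / curve, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def __call__(self, observation: Observation) -> np.ndarray:
        env = self.env
        tree = env.tree
        tip = env.tip_position()
        remaining = geodesic_distance(tree, tip, env.target,
                                      metric=env.config.pathlength_metric)
        near = tree.nearest_node(tip)
        on_distractor = tree.branch_label[near] == DISTRACTOR_BRANCH

        max_rot_step = env.config.max_rotation_speed * env.config.dt
        rot_cmd = 0.0
        slow = 1.0
        if self.bif_node is not None:
            to_bif = tree.path_between(near, self.bif_node)
            past_bif = tree.branch_label[near] != "trunk"
            if on_distractor:
                # wrong branch: retract while holding the corrective rotation
                err = self._wrapped_err(self._desired_rotation())
                rot_cmd = np.clip(err / max_rot_step, -1.0, 1.0)
                trans = -1.0
                return np.array([rot_cmd, trans, 0.0, -0.5])
            if not past_bif and to_bif <= self.lookahead:
                err = self._wrapped_err(self._desired_rotation())
                rot_cmd = np.clip(err / max_rot_step, -1.0, 1.0)
                if abs(err) > 10.0:
                    slow = 0.25  # let the rotation complete before committing
            elif past_bif:
                # back to neutral so the curved tip stops loading the wall
                err = self._wrapped_err(90.0)
                rot_cmd = np.clip(err / max_rot_step, -1.0, 1.0)

        trans = float(np.clip(remaining / self.slow_radius, 0.1, 1.0)) * slow
        return np.array([rot_cmd, trans, 0.0, 0.6 * trans])

    def _wrapped_err(self, desired: float) -> float:
        err = (desired - self.env.guidewire.axial_rotation + 180.0) % 360.0 - 180.0
        return float(err)


def oracle_policy(observation: Observation, tree: CenterlineTree,
                  target: TargetSpec, env: NavigationEnv) -> np.ndarray:
    """Functional form of the oracle; the env argument carries device state."""
    return OraclePolicy(env)(observation)


def run_oracle_episode(tree: CenterlineTree, target: TargetSpec,
                       config: EnvConfig | None = None, seed: int = 0) -> Demonstration:
    env = NavigationEnv(config)
    obs = env.reset(tree, target, seed=seed)
    policy = OraclePolicy(env)
    init_gp = obs.guidewire_points.copy()
    init_cp = obs.catheter_points.copy()
    steps: list[DemoStep] = []
    reached = False
    while not env.done:
        action = policy(obs)
        res = env.step(action)
        obs = res.observation
        steps.append(DemoStep(
            action=np.asarray(action, float),
            guidewire_points=obs.guidewire_points.copy(),
            catheter_points=obs.catheter_points.copy(),
            force_magnitude=float(np.linalg.norm(res.tip_force)),
        ))
        reached = res.reached
    return Demonstration(
        case_id=tree.case_id, target=target,
        initial_guidewire_points=init_gp, initial_catheter_points=init_cp,
        steps=steps, outcome="success" if reached else "timeout")


def record_demos(trees: list[CenterlineTree], targets_per_branch: int = 2,
                 navigations_per_case: int = 4, seed: int = 0,
                 config: EnvConfig | None = None) -> list[Demonstration]:
    """Record the demonstration protocol: per case, ``targets_per_branch``
    random targets on its side, repeated so each case contributes
    ``navigations_per_case`` navigations. Timed-out demonstrations are kept
    but flagged; IRL training excludes them."""
    rng = np.random.default_rng(seed)
    repeats = navigations_per_case // targets_per_branch
    demos: list[Demonstration] = []
    for tree in trees:
        for _ in range(targets_per_branch):
            target = sample_target(tree, seed=int(rng.integers(2**31 - 1)))
            for _ in range(repeats):
                demo = run_oracle_episode(tree, target, config,
                                          seed=int(rng.integers(2**31 - 1)))
                if demo.outcome != "success":
                    warnings.warn(
                        f"demonstration on {tree.case_id} timed out; "
                        "it will be excluded from IRL training")
                demos.append(demo)
    return demos


def split_by_side(demos: list[Demonstration]) -> dict[str, list[Demonstration]]:
    out = {"left": [], "right": []}
    for d in demos:
        out[d.target.branch_side].append(d)
    return out


# ---------------------------------------------------------------------------
# observation reconstruction (for IRL feature extraction)
# ---------------------------------------------------------------------------

def demo_observations(demo: Demonstration) -> list[Observation]:
    """Rebuild the observation the demonstrator acted on at each step."""
    target = np.asarray(demo.target.position, float)
    obs_list = []
    gp, cp = demo.initial_guidewire_points, demo.initial_catheter_points
    prev_gp, prev_cp = gp, cp
    prev_action = np.zeros(4)
    for step in demo.steps:
        obs_list.append(Observation(
            guidewire_points=gp.copy(), catheter_points=cp.copy(),
            prev_guidewire_points=prev_gp.copy(), prev_catheter_points=prev_cp.copy(),
            target=target.copy(), prev_action=prev_action.copy()))
        prev_gp, prev_cp = gp, cp
        gp, cp = step.guidewire_points, step.catheter_points
        prev_action = step.action
    return obs_list


# ---------------------------------------------------------------------------
# file I/O  (.demo.tsv: '# <json>' header line, then TSV)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.6f}"


def write_demo(demo: Demonstration, path: str | Path) -> None:
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        "case_id": demo.case_id,
        "target": {"position": [round(float(v), 6) for v in demo.target.position],
                   "branch_side": demo.target.branch_side,
                   "centerline_index": demo.target.centerline_index},
        "outcome": demo.outcome,
        "initial_guidewire_points": [[round(float(v), 6) for v in p]
                                     for p in demo.initial_guidewire_points],
        "initial_catheter_points": [[round(float(v), 6) for v in p]
                                    for p in demo.initial_catheter_points],
    }
    cols = (["step"] + [f"a{i}" for i in range(4)]
            + [f"gw{i}{c}" for i in range(3) for c in "xy"]
            + [f"cath{i}{c}" for i in range(3) for c in "xy"]
            + ["force"])
    lines = ["# " + json.dumps(header, sort_keys=True), "\t".join(cols)]
    for t, s in enumerate(demo.steps):
        row = ([str(t)] + [_fmt(v) for v in s.action]
               + [_fmt(v) for v in s.guidewire_points.ravel()]
               + [_fmt(v) for v in s.catheter_points.ravel()]
               + [_fmt(s.force_magnitude)])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_demo(path: str | Path) -> Demonstration:
    text = Path(path).read_text().strip().split("\n")
    header = json.loads(text[0][2:])
    steps = []
    for line in text[2:]:
        v = line.split("\t")
        steps.append(DemoStep(
            action=np.array([float(x) for x in v[1:5]]),
            guidewire_points=np.array([float(x) for x in v[5:11]]).reshape(3, 2),
            catheter_points=np.array([float(x) for x in v[11:17]]).reshape(3, 2),
            force_magnitude=float(v[17])))
    t = header["target"]
    return Demonstration(
        case_id=header["case_id"],
        target=TargetSpec(position=tuple(t["position"]),
                          branch_side=t["branch_side"],
                          centerline_index=t["centerline_index"]),
        initial_guidewire_points=np.array(header["initial_guidewire_points"], float),
        initial_catheter_points=np.array(header["initial_catheter_points"], float),
        steps=steps, outcome=header["outcome"])
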