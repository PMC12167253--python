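"""Two-device navigation environment on a synthetic vessel tree.

A micro-guidewire (curved tip, steered by axial rotation) and a micro-catheter
(riding over the wire) are driven by proximal rotation/translation commands.
The finite-element beam mechanics of the real simulator are replaced by a
follow-the-leader kinematic surrogate: the device body occupies the centerline
route traced by the tip, the curved tip's effective in-plane deflection is set
by axial rotation, branch selection at bifurcations follows tangent alignment,
and tip force is a linear penetration-depth proxy evaluated at the unconstrained
tip position.

The episodic contract is reset/step with explicit seed control; observations
are 2-D tracked points (three per device, 2 mm apart), the target position and
the previous action — exactly what a fluoroscopy-tracking agent would see.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .vasculature import CenterlineTree, TargetSpec, geodesic_distance

GUIDEWIRE = "guidewire"
CATHETER = "catheter"


class TaskError(ValueError):
    """Target/tree mismatch at reset."""


class LifecycleError(RuntimeError):
    """step() called on a finished or un-reset environment."""


@dataclass(frozen=True)
class EnvConfig:
    """Environment constants. Defaults are the navigation task's printed values.

    ``dt`` is derived as 27 s / 200 steps. ``wall_stiffness`` converts the
    penetration depth of the unconstrained tip beyond the lumen wall into a
    force magnitude; it is calibrated so that a careful centerline-following
    demonstrator stays at or below 0.80 N on default trees.
    """

    dt: float = 0.135                     # s per control step
    max_rotation_speed: float = 180.0     # deg/s
    max_translation_speed: float = 40.0   # mm/s
    success_threshold: float = 5.0        # mm, tip-to-target Euclidean
    timeout_steps: int = 200
    tracked_point_spacing: float = 2.0    # mm along the device body
    n_tracked_points: int = 3
    wall_stiffness: float = 1.25          # N per mm of penetration
    tip_curve_angle: float = 45.0         # deg, fixed curve of the guidewire tip
    tip_probe_length: float = 3.0         # mm, lever arm of the curved tip
    guidewire_stiffness: float = 47.0     # relative (Young's modulus scale)
    catheter_stiffness: float = 43.0
    initial_insertion: float = 5.0        # mm of wire beyond the platform at reset
    pathlength_metric: str = "centerline"  # or "euclidean"

    def __post_init__(self):
        if abs(self.dt * self.timeout_steps - 27.0) > 0.27:
            raise ValueError("dt * timeout_steps must be ~27 s (within 1%)")
        for name in ("dt", "max_rotation_speed", "max_translation_speed",
                     "success_threshold", "tracked_point_spacing", "wall_stiffness",
                     "tip_probe_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnvConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        return replace(cls(), **overrides)


@dataclass
class DeviceState:
    insertion_length: float       # mm
    axial_rotation: float         # deg, wraps mod 360; 90 deg = neutral (tip out of plane)
    route: list[int]              # centerline node indices traced from the root
    route_arc: list[float]        # cumulative arc length at each route node


@dataclass
class Observation:
    guidewire_points: np.ndarray       # (3, 2) tip first
    catheter_points: np.ndarray
    prev_guidewire_points: np.ndarray
    prev_catheter_points: np.ndarray
    target: np.ndarray                 # (2,)
    prev_action: np.ndarray            # (4,)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([
            self.guidewire_points.ravel(), self.catheter_points.ravel(),
            self.prev_guidewire_points.ravel(), self.prev_catheter_points.ravel(),
            self.target, self.prev_action,
        ])

    @staticmethod
    def vector_size() -> int:
        return 4 * 6 + 2 + 4


@dataclass
class StepResult:
    observation: Observation
    tip_force: np.ndarray          # (2,) planar force vector at the guidewire tip
    reached: bool
    truncated: bool
    step_index: int
    info: dict


def _rot2(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


class NavigationEnv:
    """Reset/step environment for dual-device navigation in a CenterlineTree."""

    def __init__(self, config: EnvConfig | None = None):
        self.config = config or EnvConfig()
        self.tree: CenterlineTree | None = None
        self.target: TargetSpec | None = None
        self._done = True

    # -- lifecycle -----------------------------------------------------------
    def reset(self, tree: CenterlineTree, target: TargetSpec, seed: int = 0) -> Observation:
        if target.branch_side != tree.side:
            raise TaskError(
                f"target side {target.branch_side!r} does not match tree side {tree.side!r}")
        self.tree = tree
        self.target = target
        self._children = tree.children()
        self._dist_to_target = self._target_distance_field()
        self._rng = np.random.default_rng(seed)
        self._step_index = 0
        self._done = False

        cfg = self.config
        self.guidewire = DeviceState(
            insertion_length=cfg.initial_insertion, axial_rotation=90.0,
            route=[0], route_arc=[0.0])
        self.catheter = DeviceState(
            insertion_length=max(cfg.initial_insertion - 2.0, 0.0),
            axial_rotation=90.0, route=[0], route_arc=[0.0])
        self._extend_route(self.guidewire)
        self._prev_action = np.zeros(4)
        gp = self.track_points(GUIDEWIRE)
        cp = self.track_points(CATHETER)
        self._prev_gp, self._prev_cp = gp.copy(), cp.copy()
        self._pathlength = self._tip_pathlength()
        return self._observation(gp, cp)

    def step(self, action) -> StepResult:
        if self._done:
            raise LifecycleError("episode finished; call reset()")
        a = np.asarray(action, dtype=float).ravel()
        if a.shape != (4,) or not np.all(np.isfinite(a)):
            raise ValueError(f"action must be a finite 4-vector, got {action!r}")
        a = np.clip(a, -1.0, 1.0)
        cfg = self.config

        self._prev_gp = self.track_points(GUIDEWIRE)
        self._prev_cp = self.track_points(CATHETER)

        gw, cath = self.guidewire, self.catheter
        gw.axial_rotation = (gw.axial_rotation + a[0] * cfg.max_rotation_speed * cfg.dt) % 360.0
        gw.insertion_length = max(
            gw.insertion_length + a[1] * cfg.max_translation_speed * cfg.dt, 0.0)
        cath.axial_rotation = (cath.axial_rotation + a[2] * cfg.max_rotation_speed * cfg.dt) % 360.0
        cath.insertion_length = max(
            cath.insertion_length + a[3] * cfg.max_translation_speed * cfg.dt, 0.0)

        self._extend_route(gw)
        self._trim_route(gw)
        # guidewire leads: the catheter cannot pass the wire tip
        cath.insertion_length = min(cath.insertion_length, gw.insertion_length)
        cath.route = gw.route
        cath.route_arc = gw.route_arc

        force = self.compute_tip_force()
        self._step_index += 1
        self._prev_action = a.copy()

        tip = self._arc_point(gw, gw.insertion_length)
        reached = bool(np.linalg.norm(tip - np.asarray(self.target.position))
                       <= cfg.success_threshold)
        truncated = (not reached) and self._step_index >= cfg.timeout_steps
        self._done = reached or truncated

        new_pathlength = self._tip_pathlength()
        delta = new_pathlength - self._pathlength
        self._pathlength = new_pathlength

        gp = self.track_points(GUIDEWIRE)
        cp = self.track_points(CATHETER)
        return StepResult(
            observation=self._observation(gp, cp),
            tip_force=force,
            reached=reached,
            truncated=truncated,
            step_index=self._step_index,
            info={
                "pathlength": new_pathlength,
                "delta_pathlength": delta,
                "applied_speeds": {
                    "guidewire_rotation_dps": a[0] * cfg.max_rotation_speed,
                    "guidewire_translation_mmps": a[1] * cfg.max_translation_speed,
                    "catheter_rotation_dps": a[2] * cfg.max_rotation_speed,
                    "catheter_translation_mmps": a[3] * cfg.max_translation_speed,
                },
            },
        )

    # -- kinematics ----------------------------------------------------------
    def _tip_heading(self) -> np.ndarray:
        """Unit direction of the curved tip: local tangent rotated by the
        effective in-plane deflection tip_curve_angle * cos(axial_rotation)."""
        gw = self.guidewire
        tangent = self._arc_tangent(gw, gw.insertion_length)
        deflection = self.config.tip_curve_angle * np.cos(np.deg2rad(gw.axial_rotation))
        return _rot2(deflection) @ tangent

    def _extend_route(self, dev: DeviceState) -> None:
        """Grow the traced route while the tip arc length exceeds it; at
        bifurcations pick the child whose tangent best aligns with the tip
        heading. At a leaf the tip is clamped to the vessel end."""
        tree = self.tree
        while dev.insertion_length > dev.route_arc[-1] + 1e-12:
            last = dev.route[-1]
            kids = self._children[last]
            if not kids:
                dev.insertion_length = dev.route_arc[-1]
                break
            if len(kids) == 1:
                nxt = kids[0]
            else:
                heading = self._tip_heading()
                best, best_dot = kids[0], -np.inf
                for k in kids:
                    d = tree.nodes[k] - tree.nodes[last]
                    d = d / (np.linalg.norm(d) + 1e-12)
                    dot = float(d @ heading)
                    if dot > best_dot:
                        best, best_dot = k, dot
                nxt = best
            dev.route.append(nxt)
            dev.route_arc.append(
                dev.route_arc[-1] + float(np.linalg.norm(tree.nodes[nxt] - tree.nodes[last])))

    def _trim_route(self, dev: DeviceState) -> None:
        while len(dev.route) > 1 and dev.insertion_length < dev.route_arc[-2] - 1e-12:
            dev.route.pop()
            dev.route_arc.pop()

    def _arc_point(self, dev: DeviceState, s: float) -> np.ndarray:
        """Point at arc length ``s`` along the device route (clamped)."""
        s = float(np.clip(s, 0.0, dev.route_arc[-1]))
        arc = dev.route_arc
        j = int(np.searchsorted(arc, s))
        if j == 0:
            return self.tree.nodes[dev.route[0]].copy()
        a, b = dev.route[j - 1], dev.route[j]
        seg = arc[j] - arc[j - 1]
        t = (s - arc[j - 1]) / seg if seg > 0 else 0.0
        return (1 - t) * self.tree.nodes[a] + t * self.tree.nodes[b]

    def _arc_tangent(self, dev: DeviceState, s: float) -> np.ndarray:
        if len(dev.route) < 2:
            return np.array([0.0, 1.0])
        s = float(np.clip(s, 0.0, dev.route_arc[-1]))
        arc = dev.route_arc
        j = max(int(np.searchsorted(arc, s)), 1)
        d = self.tree.nodes[dev.route[j]] - self.tree.nodes[dev.route[j - 1]]
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 1.0])

    # -- sensing -------------------------------------------------------------
    def track_points(self, device: str) -> np.ndarray:
        """Three tracked points: the tip, then 2 mm and 4 mm behind it along
        the body. A device shorter than the span is padded with the insertion
        point."""
        dev = self.guidewire if device == GUIDEWIRE else self.catheter
        cfg = self.config
        pts = []
        for i in range(cfg.n_tracked_points):
            s = dev.insertion_length - i * cfg.tracked_point_spacing
            pts.append(self._arc_point(dev, max(s, 0.0)))
        return np.asarray(pts)

    def compute_tip_force(self) -> np.ndarray:
        """Linear penetration proxy at the guidewire tip.

        The unconstrained tip is the tip advanced one probe length along the
        curved-tip heading; its penetration beyond the local lumen wall,
        times wall_stiffness, is the force magnitude, directed along the
        inward wall normal."""
        gw = self.guidewire
        cfg = self.config
        tip = self._arc_point(gw, gw.insertion_length)
        free_tip = tip + cfg.tip_probe_length * self._tip_heading()
        dist, idx = self.tree.kdtree().query(free_tip)
        penetration = float(dist) - float(self.tree.radius[idx])
        if penetration <= 0.0:
            return np.zeros(2)
        inward = self.tree.nodes[idx] - free_tip
        inward = inward / (np.linalg.norm(inward) + 1e-12)
        return cfg.wall_stiffness * penetration * inward

    def _target_distance_field(self) -> np.ndarray:
        """Along-tree distance from every node to the target node, computed
        once per episode by traversing the undirected tree from the target."""
        tree = self.tree
        n = len(tree.nodes)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i in range(1, n):
            p = int(tree.parent[i])
            w = float(np.linalg.norm(tree.nodes[i] - tree.nodes[p]))
            adj[i].append((p, w))
            adj[p].append((i, w))
        t_node = tree.nearest_node(np.asarray(self.target.position))
        dist = np.full(n, np.inf)
        dist[t_node] = 0.0
        stack = [t_node]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if dist[u] + w < dist[v]:
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    def _tip_pathlength(self) -> float:
        tip = self._arc_point(self.guidewire, self.guidewire.insertion_length)
        if self.config.pathlength_metric == "euclidean":
            return float(np.linalg.norm(tip - np.asarray(self.target.position)))
        return float(self._dist_to_target[self.tree.nearest_node(tip)])

    def _observation(self, gp: np.ndarray, cp: np.ndarray) -> Observation:
        return Observation(
            guidewire_points=gp, catheter_points=cp,
            prev_guidewire_points=self._prev_gp.copy(),
            prev_catheter_points=self._prev_cp.copy(),
            target=np.asarray(self.target.position, dtype=float),
            prev_action=self._prev_action.copy(),
        )

    # -- conveniences --------------------------------------------------------
    @property
    def done(self) -> bool:
        return self._done

    @property
    def step_index(self) -> int:
        return self._step_index

    @property
    def pathlength(self) -> float:
        return self._pathlength

    def tip_position(self) -> np.ndarray:
        return self._arc_point(self.guidewire, self.guidewire.insertion_length)
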