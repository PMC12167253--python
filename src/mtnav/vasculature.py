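"""Synthetic bifurcating vascular trees for dual-device navigation.

Each tree is a planar stand-in for the intracranial segment navigated in the
second stage of mechanical thrombectomy: a tortuous trunk (internal carotid
artery analogue) that bifurcates into a target branch (middle cerebral artery
analogue) and a distractor branch (anterior cerebral artery analogue). Geometry
is 2-D centerlines with lumen radii, resampled at a fixed step so arc-length
queries are well conditioned.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

RESAMPLE_STEP_MM = 0.5

TRUNK = "trunk"
TARGET_BRANCH = "target_branch"
DISTRACTOR_BRANCH = "distractor_branch"


class ParameterError(ValueError):
    """A tree-shape parameter is outside its valid range."""


class GeometryError(ValueError):
    """A geometric precondition is violated (e.g. branch too short)."""


@dataclass(frozen=True)
class TreeParams:
    """Shape parameters of the synthetic vessel tree (all lengths in mm).

    Defaults approximate the cervical-to-M1 segment at adult scale: an ~80 mm
    trunk with gentle sinusoidal tortuosity, a ~70 degree bifurcation, and a
    target branch long enough to host ten candidate target points.
    """

    trunk_length: float = 80.0
    tortuosity_amplitude: float = 5.0
    tortuosity_frequency: float = 1.5  # sinusoid periods along the trunk
    bifurcation_angle: float = 70.0    # degrees between the two daughter branches
    target_branch_length: float = 45.0
    distractor_branch_length: float = 40.0
    trunk_radius: float = 2.0
    branch_radius: float = 1.5
    side: str = "right"
    jitter: float = 0.15  # relative seed-to-seed variation of shape parameters

    def validate(self) -> None:
        for name in ("trunk_length", "target_branch_length",
                     "distractor_branch_length", "trunk_radius", "branch_radius"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.tortuosity_amplitude < 0:
            raise ParameterError("tortuosity_amplitude must be >= 0")
        if not 0.0 < self.bifurcation_angle < 180.0:
            raise ParameterError(
                f"bifurcation_angle must be in (0, 180) degrees, got {self.bifurcation_angle}")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")


@dataclass
class CenterlineTree:
    """Labelled planar centerline tree.

    ``nodes[i]`` is a 2-D point (mm); ``parent[i]`` indexes the parent node
    (-1 for the root, which is node 0, the insertion point). ``branch_label[i]``
    labels the edge parent->i (the root carries the trunk label).
    """

    nodes: np.ndarray            # (N, 2)
    parent: np.ndarray           # (N,) int
    radius: np.ndarray           # (N,)
    branch_label: list[str]
    side: str
    case_id: str
    rng_seed: int
    params: TreeParams
    _kdtree: cKDTree | None = field(default=None, repr=False, compare=False)
    _droot: np.ndarray | None = field(default=None, repr=False, compare=False)
    _depth: np.ndarray | None = field(default=None, repr=False, compare=False)

    # -- cached geometry -----------------------------------------------------
    def kdtree(self) -> cKDTree:
        if self._kdtree is None:
            self._kdtree = cKDTree(self.nodes)
        return self._kdtree

    def dist_to_root(self) -> np.ndarray:
        """Arc length from the root to every node, following parent edges."""
        if self._droot is None:
            d = np.zeros(len(self.nodes))
            for i in range(1, len(self.nodes)):
                p = self.parent[i]
                d[i] = d[p] + np.linalg.norm(self.nodes[i] - self.nodes[p])
            self._droot = d
        return self._droot

    def depth(self) -> np.ndarray:
        if self._depth is None:
            d = np.zeros(len(self.nodes), dtype=int)
            for i in range(1, len(self.nodes)):
                d[i] = d[self.parent[i]] + 1
            self._depth = d
        return self._depth

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in self.nodes]
        for i in range(1, len(self.nodes)):
            ch[self.parent[i]].append(i)
        return ch

    def nearest_node(self, point) -> int:
        return int(self.kdtree().query(np.asarray(point, float))[1])

    def branch_nodes(self, label: str) -> np.ndarray:
        """Indices on the given branch, ordered proximal to distal."""
        idx = np.array([i for i, lab in enumerate(self.branch_label) if lab == label],
                       dtype=int)
        return idx[np.argsort(self.dist_to_root()[idx])]

    def path_between(self, u: int, v: int) -> float:
        """Arc-length distance between two nodes along the unique tree path."""
        droot = self.dist_to_root()
        depth = self.depth()
        a, b = u, v
        while depth[a] > depth[b]:
            a = self.parent[a]
        while depth[b] > depth[a]:
            b = self.parent[b]
        while a != b:
            a = self.parent[a]
            b = self.parent[b]
        return float(droot[u] + droot[v] - 2.0 * droot[a])


@dataclass(frozen=True)
class TargetSpec:
    """One of the candidate target points on the target branch."""

    position: tuple[float, float]
    branch_side: str
    centerline_index: int


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _resample_polyline(points: np.ndarray, step: float = RESAMPLE_STEP_MM) -> np.ndarray:
    """Resample a polyline at a fixed arc-length step, keeping both endpoints."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.ceil(total / step)), 1)
    snew = np.linspace(0.0, total, n + 1)
    x = np.interp(snew, s, points[:, 0])
    y = np.interp(snew, s, points[:, 1])
    return np.column_stack([x, y])


def _rot(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def generate_tree(params: TreeParams | None = None, seed: int = 0) -> CenterlineTree:
    """Generate one synthetic vessel tree; pure function of (params, seed)."""
    params = params or TreeParams()
    params.validate()
    rng = np.random.default_rng(seed)

    def jit(x: float) -> float:
        return x * (1.0 + params.jitter * rng.uniform(-1.0, 1.0))

    trunk_len = jit(params.trunk_length)
    amp = params.tortuosity_amplitude * (1.0 + params.jitter * rng.uniform(-1.0, 1.0)) \
        if params.tortuosity_amplitude > 0 else 0.0
    freq = jit(params.tortuosity_frequency)
    bif_angle = np.clip(jit(params.bifurcation_angle), 1.0, 179.0)
    target_len = jit(params.target_branch_length)
    distractor_len = jit(params.distractor_branch_length)
    phase = rng.uniform(0.0, 2.0 * np.pi)

    # trunk: y increases distally, sinusoidal lateral excursion
    t = np.linspace(0.0, trunk_len, 400)
    x = amp * np.sin(2.0 * np.pi * freq * t / trunk_len + phase)
    x -= x[0]  # root at the origin
    trunk = _resample_polyline(np.column_stack([x, t]))

    tangent = trunk[-1] - trunk[-2]
    tangent = tangent / np.linalg.norm(tangent)
    lateral_sign = 1.0 if params.side == "right" else -1.0
    # target branch turns laterally; distractor continues medially
    target_turn = lateral_sign * 0.55 * bif_angle
    distractor_turn = -lateral_sign * 0.45 * bif_angle

    def make_branch(turn_deg: float, length: float, curvature_deg: float) -> np.ndarray:
        """Arc of constant curvature leaving the bifurcation at ``turn_deg``."""
        n = 200
        step = length / n
        heading = _rot(turn_deg) @ tangent
        pts = [trunk[-1]]
        for _ in range(n):
            pts.append(pts[-1] + heading * step)
            heading = _rot(curvature_deg / n) @ heading
        return _resample_polyline(np.asarray(pts))[1:]  # drop shared bifurcation point

    curve_t = lateral_sign * rng.uniform(5.0, 20.0)
    curve_d = -lateral_sign * rng.uniform(0.0, 10.0)
    target = make_branch(target_turn, target_len, curve_t)
    distractor = make_branch(distractor_turn, distractor_len, curve_d)

    nodes = [trunk, target, distractor]
    n_trunk, n_t, n_d = len(trunk), len(target), len(distractor)
    parent = np.concatenate([
        np.arange(-1, n_trunk - 1),
        [n_trunk - 1], np.arange(n_trunk, n_trunk + n_t - 1),
        [n_trunk - 1], np.arange(n_trunk + n_t, n_trunk + n_t + n_d - 1),
    ]).astype(int)
    labels = ([TRUNK] * n_trunk + [TARGET_BRANCH] * n_t + [DISTRACTOR_BRANCH] * n_d)

    # radii taper linearly within each segment
    r_trunk = np.linspace(params.trunk_radius, params.trunk_radius * 0.85, n_trunk)
    r_t = np.linspace(params.branch_radius, params.branch_radius * 0.8, n_t)
    r_d = np.linspace(params.branch_radius * 0.9, params.branch_radius * 0.7, n_d)

    return CenterlineTree(
        nodes=np.vstack(nodes),
        parent=parent,
        radius=np.concatenate([r_trunk, r_t, r_d]),
        branch_label=labels,
        side=params.side,
        case_id=f"case_{params.side}_{seed:04d}",
        rng_seed=seed,
        params=params,
    )


def generate_straight_tree(length: float = 100.0, radius: float = 2.0,
                           side: str = "right", target_fraction: float = 0.5,
                           seed: int = 0) -> CenterlineTree:
    """A single straight vessel with no bifurcation: the distal part carries
    the target-branch label. Used for curriculum and convergence checks."""
    if length <= 0 or radius <= 0:
        raise ParameterError("length and radius must be positive")
    pts = _resample_polyline(np.array([[0.0, 0.0], [0.0, length]]))
    n = len(pts)
    split = int(n * (1.0 - target_fraction))
    labels = [TRUNK] * split + [TARGET_BRANCH] * (n - split)
    return CenterlineTree(
        nodes=pts,
        parent=np.arange(-1, n - 1),
        radius=np.full(n, radius),
        branch_label=labels,
        side=side,
        case_id=f"straight_{side}_{seed:04d}",
        rng_seed=seed,
        params=TreeParams(trunk_length=length, tortuosity_amplitude=0.0,
                          side=side),
    )


def check_tree(tree: CenterlineTree) -> list[str]:
    """Return a list of invariant violations (empty when the tree is valid)."""
    issues = []
    roots = np.flatnonzero(tree.parent < 0)
    if len(roots) != 1 or roots[0] != 0:
        issues.append("tree must have exactly one root at node 0")
    if np.any(tree.parent[1:] >= np.arange(1, len(tree.nodes))):
        issues.append("parent indices must precede children (acyclic ordering)")
    if np.any(tree.radius <= 0):
        issues.append("all radii must be positive")
    gaps = np.linalg.norm(
        tree.nodes[1:] - tree.nodes[tree.parent[1:]], axis=1)
    if np.any(gaps > 1.0 + 1e-9):
        issues.append(f"consecutive centerline points exceed 1 mm (max {gaps.max():.3f})")
    target_idx = tree.branch_nodes(TARGET_BRANCH)
    if len(target_idx) == 0:
        issues.append("no target_branch edges")
    else:
        # the target branch must form a single root-descending chain
        chain = set(target_idx)
        heads = [i for i in target_idx if tree.parent[i] not in chain]
        if len(heads) != 1:
            issues.append("target_branch must be a single contiguous path")
    return issues


# ---------------------------------------------------------------------------
# targets, augmentation, geodesics
# ---------------------------------------------------------------------------

def target_candidates(tree: CenterlineTree, n_points: int = 10) -> np.ndarray:
    """The ``n_points`` equally spaced candidate points along the target branch."""
    idx = tree.branch_nodes(TARGET_BRANCH)
    if len(idx) < n_points:
        raise GeometryError(
            f"target branch has {len(idx)} points; {n_points} required")
    droot = tree.dist_to_root()
    s = droot[idx] - droot[idx[0]]
    fractions = (np.arange(n_points) + 1) / n_points
    want = fractions * s[-1]
    xs = np.interp(want, s, tree.nodes[idx, 0])
    ys = np.interp(want, s, tree.nodes[idx, 1])
    return np.column_stack([xs, ys])


def sample_target(tree: CenterlineTree, n_points: int = 10, seed: int = 0) -> TargetSpec:
    """Sample one of ``n_points`` equally spaced target-branch points uniformly."""
    cand = target_candidates(tree, n_points)
    k = int(np.random.default_rng(seed).integers(n_points))
    return TargetSpec(position=(float(cand[k, 0]), float(cand[k, 1])),
                      branch_side=tree.side, centerline_index=k)


def target_by_index(tree: CenterlineTree, index: int, n_points: int = 10) -> TargetSpec:
    cand = target_candidates(tree, n_points)
    return TargetSpec(position=(float(cand[index, 0]), float(cand[index, 1])),
                      branch_side=tree.side, centerline_index=index)


def augment_scale(tree: CenterlineTree, sx: float, sy: float) -> CenterlineTree:
    """Anisotropic rescaling about the root; radii scale by mean(sx, sy)."""
    for name, v in (("sx", sx), ("sy", sy)):
        if not 0.7 <= v <= 1.3:
            raise ParameterError(f"{name} must lie in [0.7, 1.3], got {v}")
    root = tree.nodes[0]
    nodes = (tree.nodes - root) * np.array([sx, sy]) + root
    return CenterlineTree(
        nodes=nodes,
        parent=tree.parent.copy(),
        radius=tree.radius * (0.5 * (sx + sy)),
        branch_label=list(tree.branch_label),
        side=tree.side,
        case_id=tree.case_id,
        rng_seed=tree.rng_seed,
        params=tree.params,
    )


def geodesic_distance(tree: CenterlineTree, point, target: TargetSpec,
                      metric: str = "centerline") -> float:
    """Distance from ``point`` to the target.

    ``centerline`` (default) measures along the tree: the point and the target
    are projected to their nearest centerline nodes and the unique tree path
    between them is measured; this decreases monotonically along a correct
    route past the bifurcation. ``euclidean`` is the straight-line distance.
    """
    p = np.asarray(point, dtype=float)
    if metric == "euclidean":
        return float(np.linalg.norm(p - np.asarray(target.position)))
    u = tree.nearest_node(p)
    v = tree.nearest_node(np.asarray(target.position))
    return tree.path_between(u, v)


# ---------------------------------------------------------------------------
# dataset + file I/O
# ---------------------------------------------------------------------------

def generate_dataset(n_cases: int = 12, seed: int = 0,
                     params: TreeParams | None = None) -> list[CenterlineTree]:
    """Generate a cohort of trees, alternating sides, with per-case seeds."""
    base = params or TreeParams()
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    trees = []
    for i, cs in enumerate(case_seeds):
        side = "right" if i % 2 == 0 else "left"
        trees.append(generate_tree(replace(base, side=side), seed=int(cs)))
    return trees


def train_test_split(trees: list[CenterlineTree],
                     n_test: int = 2) -> tuple[list[CenterlineTree], list[CenterlineTree]]:
    """Hold out the last ``n_test`` cases (one per side when alternating)."""
    return trees[:-n_test], trees[-n_test:]


def write_tree(tree: CenterlineTree, path: str | Path) -> None:
    """Write ``<stem>.ctl.tsv`` plus a ``<stem>.ctl.json`` sidecar."""
    path = Path(path)
    stem = path.with_suffix("").with_suffix("") if path.name.endswith(".ctl.tsv") else path
    tsv = stem.with_suffix(".ctl.tsv")
    lines = ["case_id\tnode_id\tparent_id\tx\ty\tradius\tbranch_label\tside"]
    for i in range(len(tree.nodes)):
        lines.append("\t".join([
            tree.case_id, str(i), str(int(tree.parent[i])),
            f"{tree.nodes[i, 0]:.6f}", f"{tree.nodes[i, 1]:.6f}",
            f"{tree.radius[i]:.6f}", tree.branch_label[i], tree.side,
        ]))
    tsv.write_text("\n".join(lines) + "\n")
    meta = {"case_id": tree.case_id, "seed": tree.rng_seed,
            "params": asdict(tree.params), "side": tree.side}
    stem.with_suffix(".ctl.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_tree(path: str | Path) -> CenterlineTree:
    path = Path(path)
    stem = Path(str(path)[:-len(".ctl.tsv")]) if str(path).endswith(".ctl.tsv") else path
    tsv = Path(str(stem) + ".ctl.tsv")
    meta = json.loads(Path(str(stem) + ".ctl.json").read_text())
    rows = [ln.split("\t") for ln in tsv.read_text().strip().split("\n")[1:]]
    nodes = np.array([[float(r[3]), float(r[4])] for r in rows])
    parent = np.array([int(r[2]) for r in rows])
    radius = np.array([float(r[5]) for r in rows])
    labels = [r[6] for r in rows]
    return CenterlineTree(
        nodes=nodes, parent=parent, radius=radius, branch_label=labels,
        side=meta["side"], case_id=meta["case_id"], rng_seed=meta["seed"],
        params=TreeParams(**meta["params"]),
    )
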