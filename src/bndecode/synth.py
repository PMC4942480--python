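"""Synthetic data generation: voxel geometries, class-conditional response
datasets with planted dependency DAGs, and BOLD-like event-related time
series.

The generator emulates the statistical structure a connectivity-aware
decoder exploits: each stimulus class shifts voxel means, and a sparse,
spatially local DAG of linear couplings between voxels induces
class-conditional dependencies on top of the naive-Bayes signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import TrialMatrix, VoxelMeta, coord_array
from .hrf import double_gamma_hrf

# Brodmann area -> lobe assignment (standard cortical anatomy).
BA_LOBE: dict[str, str] = {}
for _ba in (4, 6, 8, 9, 10, 11, 12, 24, 25, 32, 33, 44, 45, 46, 47):
    BA_LOBE[f"BA{_ba}"] = "frontal"
for _ba in (17, 18, 19):
    BA_LOBE[f"BA{_ba}"] = "occipital"
for _ba in (1, 2, 3, 5, 7, 23, 26, 29, 30, 31, 39, 40, 43):
    BA_LOBE[f"BA{_ba}"] = "parietal"
for _ba in (20, 21, 22, 27, 28, 34, 35, 36, 37, 38, 41, 42):
    BA_LOBE[f"BA{_ba}"] = "temporal"

#: voxel edge length of the acquisition the defaults emulate, in mm
DEFAULT_SPACING_MM = 2.2


def generate_voxel_geometry(
    n_voxels: int,
    ba_spec: dict[str, int],
    spacing: float = DEFAULT_SPACING_MM,
    seed: int = 0,
    jitter_frac: float = 0.3,
    lobes: dict[str, str] | None = None,
) -> list[VoxelMeta]:
    """Place ``n_voxels`` on a jittered 3-D grid, grouped into contiguous
    Brodmann-area blocks.

    Each BA in ``ba_spec`` occupies a compact cubic block; blocks are laid
    out along x with a gap, so voxels sharing a BA are spatially close and
    different BAs are separated.  Coordinates are jittered uniformly by up
    to ``jitter_frac * spacing`` per axis, so nearest-neighbour distances
    stay >= spacing * (1 - 2*jitter_frac).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    total = sum(ba_spec.values())
    if total != n_voxels:
        raise ValueError(f"ba_spec counts sum to {total}, expected n_voxels={n_voxels}")
    lobes = lobes or BA_LOBE
    rng = np.random.default_rng(seed)
    jitter = jitter_frac * spacing

    meta: list[VoxelMeta] = []
    x_offset = 0.0
    vid = 0
    for ba, count in ba_spec.items():
        side = int(np.ceil(count ** (1.0 / 3.0)))
        grid = [
            (ix, iy, iz)
            for ix in range(side)
            for iy in range(side)
            for iz in range(side)
        ][:count]
        for ix, iy, iz in grid:
            base = np.array([x_offset + ix * spacing, iy * spacing, iz * spacing])
            coord = base + rng.uniform(-jitter / 2, jitter / 2, size=3)
            lobe = lobes.get(ba, "frontal")
            meta.append(VoxelMeta(vid, tuple(coord), ba, lobe))
            vid += 1
        # distinct areas sit centimetres apart: leave an 8-grid-step gap
        x_offset += (side + 8) * spacing
    return meta


@dataclass
class GenerativeModel:
    """Ground-truth generative model for class-conditional voxel responses.

    Attribute ``i`` of a trial with class ``c`` is drawn, in topological
    order of ``edges``, as::

        x_i = class_means[c, i] + sum_p w(p->i, c) * x_p + noise_sd_i * z

    ``edge_weights`` values may be scalars (same coupling in every class) or
    length-``n_classes`` vectors (class-dependent coupling, e.g. a sign flip
    that leaves all marginals untouched).
    """

    n_classes: int
    class_means: np.ndarray  # (n_classes, n_voxels), t-value units
    edges: tuple[tuple[int, int], ...] = ()
    edge_weights: dict[tuple[int, int], object] = field(default_factory=dict)
    noise_sd: object = 1.0  # scalar or per-voxel array, > 0
    locality_scale: float = 5.0  # mm

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        if self.class_means.shape[0] != self.n_classes:
            raise ValueError("class_means row count must equal n_classes")
        sd = np.asarray(self.noise_sd, dtype=float)
        if np.any(sd <= 0):
            raise ValueError("noise_sd must be positive")
        for e in self.edge_weights:
            if e not in self.edges:
                raise ValueError(f"edge_weights refers to edge {e} absent from edges")
        g = nx.DiGraph(list(self.edges))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("dependency DAG contains a cycle")

    @property
    def n_voxels(self) -> int:
        return self.class_means.shape[1]

    def weight(self, edge: tuple[int, int], c: int) -> float:
        w = self.edge_weights.get(edge, 0.0)
        w = np.asarray(w, dtype=float)
        return float(w) if w.ndim == 0 else float(w[c])

    def noise_vector(self) -> np.ndarray:
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(self.n_voxels, float(sd))
        return sd


def random_local_dag(
    voxels: list[VoxelMeta],
    n_edges: int,
    locality_scale: float = 5.0,
    seed: int = 0,
    max_in_degree: int = 1,
) -> tuple[tuple[int, int], ...]:
    """Sample a sparse DAG whose edges prefer spatially close voxel pairs.

    Candidate pairs (i < j) are drawn without replacement with probability
    proportional to exp(-d_ij / locality_scale), d in mm; edges are oriented
    low index -> high index, which guarantees acyclicity.  ``max_in_degree``
    bounds the number of parents per node (default 1: chains and pairs only,
    so the planted adjacency is identifiable from data).
    """
    rng = np.random.default_rng(seed)
    coords = coord_array(voxels)
    n = len(voxels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    d = np.array([np.linalg.norm(coords[i] - coords[j]) for i, j in pairs])
    w = np.exp(-d / locality_scale)
    edges: list[tuple[int, int]] = []
    in_deg = np.zeros(n, dtype=int)
    order = list(rng.choice(len(pairs), size=len(pairs), replace=False, p=w / w.sum()))
    for idx in order:
        i, j = pairs[idx]
        if in_deg[j] >= max_in_degree:
            continue
        edges.append((i, j))
        in_deg[j] += 1
        if len(edges) == n_edges:
            break
    if len(edges) < n_edges:
        raise ValueError(f"could only place {len(edges)} of {n_edges} requested edges")
    return tuple(edges)


def make_generative_model(
    voxels: list[VoxelMeta],
    n_classes: int = 10,
    class_mean_sd: float = 1.0,
    n_edges: int = 0,
    edge_weight: float = 1.5,
    noise_sd: float = 1.0,
    locality_scale: float = 5.0,
    seed: int = 0,
) -> GenerativeModel:
    """Build a default generative model over the given voxel geometry.

    Class mean responses are drawn iid N(0, class_mean_sd^2) per (class,
    voxel) — a ~1 sd separation between class means against unit trial
    noise, the regime where a few hundred trials per class decode well but
    not trivially.  ``n_edges`` planted couplings of weight ``edge_weight``
    are sampled by :func:`random_local_dag`.
    """
    rng = np.random.default_rng(seed)
    means = rng.normal(0.0, class_mean_sd, size=(n_classes, len(voxels)))
    edges: tuple[tuple[int, int], ...] = ()
    weights: dict[tuple[int, int], object] = {}
    if n_edges > 0:
        edges = random_local_dag(voxels, n_edges, locality_scale, seed=seed + 1)
        weights = {e: edge_weight for e in edges}
    return GenerativeModel(
        n_classes=n_classes,
        class_means=means,
        edges=edges,
        edge_weights=weights,
        noise_sd=noise_sd,
        locality_scale=locality_scale,
    )


def generate_response_dataset(
    model: GenerativeModel,
    n_per_class: int,
    voxels: list[VoxelMeta],
    seed: int = 0,
) -> TrialMatrix:
    """Sample a balanced trial-by-voxel response dataset from ``model``.

    Exactly ``n_per_class`` trials per class, attributes sampled in
    topological order of the dependency DAG.  Deterministic given seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if model.n_voxels != len(voxels):
        raise ValueError(
            f"model has {model.n_voxels} voxels, geometry has {len(voxels)}"
        )
    rng = np.random.default_rng(seed)
    d = model.n_voxels
    g = nx.DiGraph()
    g.add_nodes_from(range(d))
    g.add_edges_from(model.edges)
    topo = list(nx.topological_sort(g))
    parents = {j: sorted(p for p, c in model.edges if c == j) for j in range(d)}
    sd = model.noise_vector()

    n = model.n_classes * n_per_class
    X = np.empty((n, d))
    y = np.repeat(np.arange(model.n_classes), n_per_class)
    noise = rng.standard_normal((n, d))
    for c in range(model.n_classes):
        rows = slice(c * n_per_class, (c + 1) * n_per_class)
        for j in topo:
            col = model.class_means[c, j] + sd[j] * noise[rows, j]
            for p in parents[j]:
                col = col + model.weight((p, j), c) * X[rows, p]
            X[rows, j] = col
    return TrialMatrix(X, y, list(voxels))


def generate_coupling_contrast_dataset(
    n_pairs: int = 4,
    n_noise_voxels: int = 0,
    n_per_class: int = 500,
    weight: float = 1.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    spacing: float = DEFAULT_SPACING_MM,
) -> tuple[TrialMatrix, GenerativeModel]:
    """Two-class dataset where the classes differ *only* in coupling sign.

    Each of ``n_pairs`` voxel pairs (A, B) has B = ±weight·A + noise with
    the sign flipped between the two classes; all class means are zero, so
    every marginal distribution is identical across classes.  A classifier
    blind to attribute dependencies (naive Bayes) is at chance here, while
    one that models the couplings can decode the class from the
    covariance sign.
    """
    d = 2 * n_pairs + n_noise_voxels
    voxels = generate_voxel_geometry(d, {"BA18": d}, spacing=spacing, seed=seed)
    edges = tuple((2 * k, 2 * k + 1) for k in range(n_pairs))
    weights = {e: np.array([weight, -weight]) for e in edges}
    model = GenerativeModel(
        n_classes=2,
        class_means=np.zeros((2, d)),
        edges=edges,
        edge_weights=weights,
        noise_sd=noise_sd,
    )
    tm = generate_response_dataset(model, n_per_class, voxels, seed=seed + 1)
    return tm, model


@dataclass
class EventTable:
    """Stimulus events: onsets and durations in seconds, one class label each."""

    onsets: np.ndarray
    durations: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.conditions = np.asarray(self.conditions)
        if not (len(self.onsets) == len(self.durations) == len(self.conditions)):
            raise ValueError("onsets, durations, conditions must have equal length")
        if np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be non-decreasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be positive")

    def __len__(self) -> int:
        return len(self.onsets)


def make_event_table(
    conditions: np.ndarray,
    stim_duration: float = 1.0,
    isi: float = 9.0,
    initial_fixation: float = 10.0,
) -> EventTable:
    """Slow event-related schedule: 1 s stimulus + 9 s gap after a 10 s
    initial fixation (one trial every ``stim_duration + isi`` seconds)."""
    conditions = np.asarray(conditions)
    onsets = initial_fixation + np.arange(len(conditions)) * (stim_duration + isi)
    return EventTable(onsets, np.full(len(conditions), stim_duration), conditions)


def generate_bold_timeseries(
    events: EventTable,
    model: GenerativeModel,
    tr: float = 2.5,
    n_scans: int = 120,
    seed: int = 0,
    noise_sd: float = 0.0,
    dt: float = 0.1,
) -> np.ndarray:
    """Simulate event-related BOLD series for every voxel of ``model``.

    Each voxel's series is a sum over events of amplitude x (HRF-convolved
    boxcar), sampled at ``tr``, plus white Gaussian noise.  The amplitude
    for an event of class ``c`` at voxel ``i`` is ``model.class_means[c, i]``.
    Returns a (n_scans, n_voxels) array.
    """
    total = n_scans * tr
    if np.any(events.onsets + events.durations > total):
        raise ValueError("event extends beyond the scan window")
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, total, dt)
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, dt))
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)

    out = np.zeros((n_scans, model.n_voxels))
    for onset, dur, cond in zip(events.onsets, events.durations, events.conditions):
        box = ((grid >= onset) & (grid < onset + dur)).astype(float)
        reg = np.convolve(box, hrf)[: len(grid)] * dt
        amp = model.class_means[int(cond)]
        out += np.outer(reg[scan_idx], amp)
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.shape)
    return out
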