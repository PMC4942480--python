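"""Similarity analysis of Brodmann areas.

Active voxels' responses are averaged per BA into one response vector per
area (one element per stimulus), pairwise dissimilarity is the correlation
distance 1 - r, and areas are grouped by complete-linkage (furthest
distance) agglomerative clustering.  The partition is read off by cutting
the tree at a fraction (default half) of the maximum pairwise distance.

The agglomeration is implemented here rather than delegated so that ties
are resolved deterministically, by the lexicographically smallest leaf
labels of the candidate pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import TrialMatrix


def ba_average_responses(
    data: TrialMatrix, active_mask: np.ndarray
) -> pd.DataFrame:
    """Mean response of each BA's active voxels to every trial.

    ``active_mask`` holds voxel ids (e.g. the union of voxels selected in
    any cross-validation fold).  Returns a DataFrame with one row per BA
    and one column per trial; BAs with no active voxels are omitted with
    a warning.
    """
    active = set(int(v) for v in np.asarray(active_mask).ravel())
    if not active:
        raise ValueError("active_mask is empty")
    groups: dict[str, list[int]] = {}
    for col, m in enumerate(data.voxel_meta):
        if m.voxel_id in active:
            groups.setdefault(m.ba, []).append(col)
    all_bas = {m.ba for m in data.voxel_meta}
    dropped = sorted(all_bas - set(groups))
    if dropped:
        warnings.warn(f"BAs with no active voxels dropped: {dropped}", stacklevel=2)
    rows = {ba: data.values[:, cols].mean(axis=1) for ba, cols in sorted(groups.items())}
    return pd.DataFrame(rows).T


def correlation_distance_matrix(M: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise correlation distance d(a, b) = 1 - Pearson r; range [0, 2],
    zero diagonal.  Raises on a constant row, naming the BA."""
    if isinstance(M, pd.DataFrame):
        labels = list(M.index)
        V = M.to_numpy(dtype=float)
    else:
        V = np.asarray(M, dtype=float)
        labels = [str(i) for i in range(V.shape[0])]
    sd = V.std(axis=1)
    bad = [labels[i] for i in np.flatnonzero(sd == 0)]
    if bad:
        raise ValueError(f"constant response rows (zero variance): {bad}")
    D = 1.0 - np.corrcoef(V)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class ClusterTree:
    """Agglomerative merge records over labelled leaves.

    ``merges[k] = (left, right, height)`` where left/right are sorted
    tuples of leaf labels and height is the complete-linkage distance at
    which they merged.  n - 1 merges for n leaves; heights non-decreasing.
    """

    leaves: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]]

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        height_of: dict[tuple[str, ...], float] = {(lf,): 0.0 for lf in self.leaves}
        text_of: dict[tuple[str, ...], str] = {(lf,): lf for lf in self.leaves}
        node = None
        for left, right, h in self.merges:
            node = tuple(sorted(left + right))
            bl_l = h - height_of[left]
            bl_r = h - height_of[right]
            text_of[node] = f"({text_of[left]}:{bl_l:g},{text_of[right]}:{bl_r:g})"
            height_of[node] = h
        return (text_of[node] if node is not None else self.leaves[0]) + ";"


def hierarchical_cluster(
    D: np.ndarray, labels: list[str] | None = None
) -> ClusterTree:
    """Complete-linkage (furthest distance) agglomerative clustering.

    Repeatedly merges the pair of clusters with the smallest inter-cluster
    distance, where the distance between clusters is the maximum pairwise
    leaf distance.  Ties go to the candidate pair with lexicographically
    smallest leaf labels.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    labels = labels or [str(i) for i in range(n)]
    idx_of = {lab: i for i, lab in enumerate(labels)}

    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def linkage(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return max(D[idx_of[x], idx_of[y]] for x in a for y in b)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                d = linkage(a, b)
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append((a, b, d))
        clusters = [c for c in clusters if c != a and c != b]
        clusters.append(tuple(sorted(a + b)))
    return ClusterTree(list(labels), merges)


def cut_clusters(
    tree: ClusterTree, D: np.ndarray, fraction: float = 0.5
) -> dict[str, int]:
    """Partition by cutting the tree at ``fraction`` of the maximum
    pairwise distance.

    The threshold is ``fraction * max(D)``; merges with height strictly
    below the threshold are applied, everything else stays separate
    (singletons allowed).  Cluster ids are numbered by each cluster's
    smallest leaf label.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    threshold = fraction * float(np.max(D))
    member_of = {lf: (lf,) for lf in tree.leaves}
    for left, right, h in tree.merges:
        if h < threshold:
            merged = tuple(sorted(left + right))
            for lf in merged:
                member_of[lf] = merged
    clusters = sorted({c for c in member_of.values()}, key=lambda c: c[0])
    cluster_id = {c: i for i, c in enumerate(clusters)}
    return {lf: cluster_id[member_of[lf]] for lf in tree.leaves}


def partition_table(assignment: dict[str, int]) -> pd.DataFrame:
    return pd.DataFrame(
        sorted(assignment.items()), columns=["ba", "cluster"]
    )
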