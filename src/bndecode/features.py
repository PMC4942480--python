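"""Fisher-score voxel selection.

The Fisher score of voxel i is the between-class spread of its class means
over the pooled within-class variance,

    f_i = sum_j n_j (mu_ij - mu_i)^2 / sum_j n_j sigma2_ij,

a supervised univariate filter: cheap, and selection on training trials
only never sees the held-out fold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

VARIANCE_FLOOR = 1e-12


@dataclass
class FisherScores:
    """Per-voxel Fisher scores plus the class statistics they derive from."""

    scores: np.ndarray  # (n_voxels,), >= 0
    classes: np.ndarray
    class_counts: np.ndarray  # n_j
    grand_means: np.ndarray  # mu_i, (n_voxels,)
    class_means: np.ndarray  # mu_ij, (n_classes, n_voxels)
    class_vars: np.ndarray  # sigma2_ij, (n_classes, n_voxels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def fisher_scores(X: np.ndarray, y: np.ndarray, ddof: int = 0) -> FisherScores:
    """Compute Fisher scores for every column of ``X``.

    ``ddof=0`` (population within-class variances) is the default;
    pass ``ddof=1`` for the n_j - 1 convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("Fisher score requires at least 2 classes")
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise ValueError(f"every class needs >= 2 trials; too few in {small.tolist()}")

    mu = X.mean(axis=0)
    cmeans = np.stack([X[y == c].mean(axis=0) for c in classes])
    cvars = np.stack([X[y == c].var(axis=0, ddof=ddof) for c in classes])
    num = (counts[:, None] * (cmeans - mu) ** 2).sum(axis=0)
    den = (counts[:, None] * cvars).sum(axis=0)
    scores = np.where(num == 0, 0.0, num / np.maximum(den, VARIANCE_FLOOR))
    return FisherScores(scores, classes, counts, mu, cmeans, cvars)


def select_top_k(scores: FisherScores | np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest-scoring voxels, ties broken by ascending
    voxel index; returned in that deterministic order."""
    s = scores.scores if isinstance(scores, FisherScores) else np.asarray(scores)
    if not 1 <= k <= len(s):
        raise ValueError(f"k={k} out of range [1, {len(s)}]")
    order = np.lexsort((np.arange(len(s)), -s))
    return order[:k]


def common_voxels(per_fold_selections: list[np.ndarray], min_folds: int = 6) -> np.ndarray:
    """Voxels selected in at least ``min_folds`` of the given fold selections.

    The default of 6 out of 10 folds is the "more than five-folds" rule
    used when tabulating commonly selected voxels across cross-validation.
    """
    if not per_fold_selections:
        raise ValueError("need at least one fold selection")
    counts: Counter = Counter()
    for sel in per_fold_selections:
        counts.update(set(np.asarray(sel).tolist()))
    return np.array(sorted(v for v, c in counts.items() if c >= min_folds), dtype=int)


def selection_counts(per_fold_selections: list[np.ndarray]) -> dict[int, int]:
    """How many folds selected each voxel."""
    counts: Counter = Counter()
    for sel in per_fold_selections:
        counts.update(set(np.asarray(sel).tolist()))
    return dict(counts)
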