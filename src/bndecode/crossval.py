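"""Decoding evaluation protocol: stratified 10-fold cross-validation with
per-fold Fisher voxel selection, an accuracy-vs-voxel-count sweep, KS
comparisons between classifiers, and a label-permutation chance baseline.

Feature selection and classifier fitting see only the training folds; the
held-out fold enters solely at evaluation, so reported accuracies are
unbiased estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .bn import SearchConfig
from .classify import (
    accuracy,
    fit_augmented_nb,
    fit_naive_bayes,
    predict,
)
from .data import TrialMatrix
from .features import fisher_scores, select_top_k

CLASSIFIERS = ("nb", "anb")


@dataclass
class FoldPlan:
    """Disjoint trial-index folds, class-balanced within each fold."""

    k: int
    folds: list[np.ndarray]
    seed: int

    def train_test(self, i: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[i]
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        return np.flatnonzero(mask), test


def make_stratified_folds(y: np.ndarray, k: int = 10, seed: int = 0) -> FoldPlan:
    """Shuffle each class with ``seed`` and deal its trials round-robin to
    ``k`` folds, so per-class counts differ by at most one across folds
    (exactly equal when divisible)."""
    y = np.asarray(y)
    if k == 1:
        warnings.warn("k=1 gives a single fold equal to all trials", stacklevel=2)
        return FoldPlan(1, [np.arange(len(y))], seed)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        small = classes[counts < k].tolist()
        raise ValueError(f"classes {small} have fewer than k={k} trials")
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))
        for pos, trial in enumerate(idx):
            folds[pos % k].append(int(trial))
    return FoldPlan(k, [np.array(sorted(f)) for f in folds], seed)


@dataclass
class CVReport:
    """Per-(classifier, voxel_count, fold) accuracies plus the selected
    voxels and learned augmenting edges of every cell."""

    records: pd.DataFrame  # columns: classifier, voxel_count, fold, accuracy
    selections: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    # (voxel_count, fold) -> selected voxel column indices
    edges: dict[tuple[str, int, int], tuple] = field(default_factory=dict)
    # (classifier, voxel_count, fold) -> augmenting edges in original voxel ids

    def summary(self) -> pd.DataFrame:
        """Mean accuracy +/- SEM per (classifier, voxel_count)."""
        g = self.records.groupby(["classifier", "voxel_count"])["accuracy"]
        out = g.agg(["mean", "std", "count"]).reset_index()
        out["sem"] = out["std"] / np.sqrt(out["count"])
        return out[["classifier", "voxel_count", "mean", "sem", "count"]]

    def accuracies(self, classifier: str) -> np.ndarray:
        return self.records.loc[
            self.records["classifier"] == classifier, "accuracy"
        ].to_numpy()


def _fit_predict(
    name: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    search: SearchConfig,
):
    if name == "nb":
        model = fit_naive_bayes(X_train, y_train, mode=search.mode)
    elif name == "anb":
        model = fit_augmented_nb(X_train, y_train, search=search)
    else:
        raise ValueError(f"unknown classifier {name!r} (expected one of {CLASSIFIERS})")
    return model, predict(model, X_test)


def run_cv_decoding(
    data: TrialMatrix,
    classifiers: tuple[str, ...] = CLASSIFIERS,
    voxel_counts: tuple[int, ...] = tuple(range(50, 551, 50)),
    folds: FoldPlan | None = None,
    search: SearchConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVReport:
    """Cross-validated decoding over a voxel-count sweep.

    For every fold and voxel count: Fisher scores on training trials only,
    top-k selection, classifier fit on the training folds, accuracy on the
    held-out fold.  The same fold plan is reused for every classifier and
    voxel count so comparisons are paired.
    """
    if max(voxel_counts) > data.n_voxels:
        raise ValueError(
            f"max voxel count {max(voxel_counts)} exceeds available voxels {data.n_voxels}"
        )
    folds = folds or make_stratified_folds(data.labels, k=k, seed=seed)
    search = search or SearchConfig()
    vox_ids = data.voxel_ids()

    rows = []
    report = CVReport(records=pd.DataFrame())
    for fold_i in range(folds.k):
        train, test = folds.train_test(fold_i, data.n_trials)
        fs = fisher_scores(data.values[train], data.labels[train])
        for count in voxel_counts:
            sel = select_top_k(fs, count)
            report.selections[(count, fold_i)] = sel
            Xtr = data.values[np.ix_(train, sel)]
            Xte = data.values[np.ix_(test, sel)]
            for name in classifiers:
                try:
                    model, pred = _fit_predict(name, Xtr, data.labels[train], Xte, search)
                except ValueError as e:
                    raise ValueError(
                        f"fold {fold_i}, voxel_count {count}, classifier {name}: {e}"
                    ) from e
                acc = accuracy(data.labels[test], pred)
                rows.append(
                    {
                        "classifier": name,
                        "voxel_count": count,
                        "fold": fold_i,
                        "accuracy": acc,
                    }
                )
                edges = tuple(
                    (int(vox_ids[sel[p]]), int(vox_ids[sel[c]]))
                    for p, c in model.augmenting_edges
                )
                report.edges[(name, count, fold_i)] = edges
    report.records = pd.DataFrame(rows)
    return report


def compare_accuracy_ks(
    acc_a: np.ndarray, acc_b: np.ndarray, alpha: float = 0.01
) -> dict:
    """Two-sample Kolmogorov-Smirnov comparison of accuracy samples."""
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if len(acc_a) == 0 or len(acc_b) == 0:
        raise ValueError("accuracy samples must be non-empty")
    res = sp_stats.ks_2samp(acc_a, acc_b)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "alpha": alpha,
    }


def chance_level(n_classes: int) -> float:
    """Theoretical chance accuracy for a balanced problem: 1 / n_classes."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    return 1.0 / n_classes


def permutation_null_accuracies(
    data: TrialMatrix,
    n_voxels: int = 100,
    n_permutations: int = 200,
    k: int = 10,
    seed: int = 0,
    classifier: str = "nb",
) -> np.ndarray:
    """Label-permutation null distribution of cross-validated mean accuracy.

    Each replicate permutes the class labels, rebuilds stratified folds,
    and runs the full per-fold Fisher-selection + classifier protocol;
    the replicate's mean held-out accuracy is recorded.  On balanced
    10-class data the replicate means concentrate at the 10% chance level.
    """
    rng = np.random.default_rng(seed)
    search = SearchConfig()
    out = np.empty(n_permutations)
    for r in range(n_permutations):
        perm = rng.permutation(data.n_trials)
        y_perm = data.labels[perm]
        folds = make_stratified_folds(y_perm, k=k, seed=int(rng.integers(2**31)))
        accs = []
        for fold_i in range(folds.k):
            train, test = folds.train_test(fold_i, data.n_trials)
            fs = fisher_scores(data.values[train], y_perm[train])
            sel = select_top_k(fs, n_voxels)
            _, pred = _fit_predict(
                classifier,
                data.values[np.ix_(train, sel)],
                y_perm[train],
                data.values[np.ix_(test, sel)],
                search,
            )
            accs.append(accuracy(y_perm[test], pred))
        out[r] = np.mean(accs)
    return out
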