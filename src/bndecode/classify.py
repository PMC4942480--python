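"""Naive Bayes and augmented naive Bayes classifiers.

Both compute, per class c,

    log P(c | a) = log P(c) + sum_i log p(a_i | parents_i(a), c) + const,

and normalize with log-sum-exp, so products over hundreds of attributes
never underflow.  Naive Bayes uses the empty attribute-edge structure;
augmented naive Bayes first learns attribute edges by BIC hill climbing
and then fits the same MLE machinery on the enlarged structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bn import (
    ConditionalDistribution,
    DAGStructure,
    Discretizer,
    ScoreTrace,
    SearchConfig,
    CPT_FLOOR,
    empty_structure,
    fit_mle,
    hill_climb_augment,
)


@dataclass
class BNClassifierModel:
    """A fitted Bayesian-network classifier."""

    structure: DAGStructure
    classes: np.ndarray
    class_prior: np.ndarray
    conditionals: list[ConditionalDistribution]
    mode: str = "continuous"
    discretizer: Discretizer | None = None
    trace: ScoreTrace | None = None

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.class_prior)) - 1.0) > 1e-9:
            raise ValueError("class prior must sum to 1")

    @property
    def n_attributes(self) -> int:
        return self.structure.n_attributes

    @property
    def augmenting_edges(self) -> tuple[tuple[int, int], ...]:
        return self.structure.edges


def fit_naive_bayes(
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "continuous",
    n_bins: int = 4,
    var_floor: float = 1e-8,
) -> BNClassifierModel:
    """Fit a naive Bayes classifier (no attribute-attribute edges)."""
    X = np.asarray(X, dtype=float)
    structure = empty_structure(X.shape[1])
    disc = None
    Xf = X
    if mode == "discrete":
        disc = Discretizer.fit(X, n_bins)
        Xf = disc.transform(X)
    classes, prior, conds = fit_mle(structure, Xf, y, mode=mode, var_floor=var_floor)
    return BNClassifierModel(structure, classes, prior, conds, mode, disc)


def fit_augmented_nb(
    X: np.ndarray,
    y: np.ndarray,
    search: SearchConfig | None = None,
    n_bins: int = 4,
) -> BNClassifierModel:
    """Fit an augmented naive Bayes classifier.

    Attribute dependencies (effective connectivities) are learned by BIC
    hill climbing and added to the naive Bayes skeleton; parameters are
    then refitted by MLE on the final structure.
    """
    search = search or SearchConfig()
    X = np.asarray(X, dtype=float)
    disc = None
    Xf = X
    if search.mode == "discrete":
        disc = Discretizer.fit(X, n_bins)
        Xf = disc.transform(X)
    structure, trace = hill_climb_augment(
        Xf,
        y,
        max_parents=search.max_parents,
        max_steps=search.max_steps,
        mode=search.mode,
        var_floor=search.var_floor,
        improvement_tol=search.improvement_tol,
    )
    classes, prior, conds = fit_mle(
        structure, Xf, y, mode=search.mode, var_floor=search.var_floor
    )
    return BNClassifierModel(structure, classes, prior, conds, search.mode, disc, trace)


def _log_likelihood_matrix(model: BNClassifierModel, X: np.ndarray) -> np.ndarray:
    """Per-trial, per-class log joint: log prior + sum of family log densities.
    Returns an (n_trials, n_classes) array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_attributes:
        raise ValueError(
            f"input has {X.shape[1]} attributes, model expects {model.n_attributes}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite attribute values")
    n = X.shape[0]
    C = len(model.classes)
    logp = np.tile(np.log(model.class_prior), (n, 1))
    if model.mode == "discrete":
        Xd = model.discretizer.transform(X) if model.discretizer is not None else X.astype(np.int64)
        for cond in model.conditionals:
            for k in range(C):
                idx = (np.full(n, k), *[Xd[:, p] for p in cond.parents], Xd[:, cond.node])
                logp[:, k] += np.log(np.maximum(cond.cpt[idx], CPT_FLOOR))
    else:
        for cond in model.conditionals:
            if cond.parents:
                mu = cond.intercepts[None, :] + X[:, cond.parents] @ cond.weights.T
            else:
                mu = np.tile(cond.intercepts, (n, 1))
            var = cond.variances[None, :]
            logp += -0.5 * (np.log(2 * np.pi * var) + (X[:, [cond.node]] - mu) ** 2 / var)
    return logp


def predict_posterior(model: BNClassifierModel, X: np.ndarray) -> np.ndarray:
    """Posterior class probabilities, rows summing to 1 (log-sum-exp
    normalization of the per-class log joints)."""
    single = np.asarray(X).ndim == 1
    logp = _log_likelihood_matrix(model, X)
    post = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    return post[0] if single else post


def predict(model: BNClassifierModel, X: np.ndarray) -> np.ndarray:
    """Most probable class per trial; ties broken by ascending class label."""
    logp = _log_likelihood_matrix(model, X)
    return model.classes[np.argmax(logp, axis=1)]


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Fraction of trials whose predicted class matches the true label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label/prediction length mismatch")
    return float(np.mean(y_true == y_pred))
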