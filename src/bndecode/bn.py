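"""Bayesian-network machinery for augmented naive Bayes decoding.

A classifier structure has a class node C (no parents) that is a parent of
every attribute, plus a learned set of attribute->attribute edges.  The
joint factorizes as P(C) * prod_i P(A_i | Pi_i, C).  Attributes enter the
conditionals either as class-conditional linear Gaussians (default: the
t-values stay continuous, each attribute regressed on its attribute
parents with per-class intercept/weights/variance) or as CPTs after
equal-frequency discretization.

Structure search is greedy hill climbing on the decomposable BIC score:
starting from the naive Bayes skeleton (no attribute edges), repeatedly
apply the best single edge insertion, deletion, or reversal until no move
improves the score.  Because BIC decomposes over families, each candidate
move rescores only the families it touches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

VAR_FLOOR = 1e-8
CPT_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class DAGStructure:
    """Attribute-edge structure of a (augmented) naive Bayes classifier.

    Only attribute->attribute edges are stored; the class node's edges to
    every attribute are implicit and immutable.
    """

    n_attributes: int
    edges: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for p, c in self.edges:
            if not (0 <= p < self.n_attributes and 0 <= c < self.n_attributes):
                raise ValueError(f"edge ({p}, {c}) out of range")
            if p == c:
                raise ValueError(f"self-edge ({p}, {c}) not allowed")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("structure contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_attributes))
        g.add_edges_from(self.edges)
        return g

    def parent_map(self) -> dict[int, tuple[int, ...]]:
        pm: dict[int, list[int]] = {i: [] for i in range(self.n_attributes)}
        for p, c in self.edges:
            pm[c].append(p)
        return {i: tuple(sorted(v)) for i, v in pm.items()}

    def adjacencies(self) -> set[frozenset[int]]:
        """Undirected edge set (orientation discarded)."""
        return {frozenset(e) for e in self.edges}


def empty_structure(n_attributes: int) -> DAGStructure:
    """The naive Bayes skeleton: no attribute-attribute edges."""
    return DAGStructure(n_attributes)


@dataclass
class ConditionalDistribution:
    """Per-class conditional distribution of one attribute given its
    attribute parents (the class parent is implicit: one parameter set per
    class).

    Continuous mode: ``intercepts`` (C,), ``weights`` (C, |parents|),
    ``variances`` (C,).  Discrete mode: ``cpt`` with axes
    (class, *parent levels, child level), rows summing to 1.
    """

    node: int
    parents: tuple[int, ...]
    intercepts: np.ndarray | None = None
    weights: np.ndarray | None = None
    variances: np.ndarray | None = None
    cpt: np.ndarray | None = None


@dataclass
class MoveRecord:
    step: int
    move: str  # "add" | "delete" | "reverse"
    edge: tuple[int, int]
    score_before: float
    score_after: float


@dataclass
class ScoreTrace:
    """Accepted hill-climbing moves with the total BIC before/after each."""

    initial_score: float
    records: list[MoveRecord] = field(default_factory=list)

    @property
    def scores(self) -> list[float]:
        return [self.initial_score] + [r.score_after for r in self.records]


# ---------------------------------------------------------------------------
# sufficient statistics (continuous / linear-Gaussian)


class GaussianSuffStats:
    """Per-class counts, means, and Gram matrices of the training data.

    Family fits and BIC contributions are O(|parents|^3) given these,
    independent of trial count, which keeps hill climbing cheap.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes, self.counts = np.unique(y, return_counts=True)
        self.n_total = len(y)
        self.n_attributes = X.shape[1]
        self.means = np.stack([X[y == c].mean(axis=0) for c in self.classes])
        self.grams = np.stack([X[y == c].T @ X[y == c] for c in self.classes])

    def family_fit(
        self, child: int, parents: tuple[int, ...], var_floor: float = VAR_FLOOR
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """Per-class MLE of child | parents: (intercepts, weights, variances,
        total log-likelihood).  Raises on a singular within-class parent
        design."""
        P = list(parents)
        C = len(self.classes)
        intercepts = np.empty(C)
        weights = np.empty((C, len(P)))
        variances = np.empty(C)
        ll = 0.0
        for k in range(C):
            n = self.counts[k]
            m = self.means[k]
            S = self.grams[k]
            G = np.empty((len(P) + 1, len(P) + 1))
            G[0, 0] = n
            G[0, 1:] = n * m[P]
            G[1:, 0] = n * m[P]
            G[1:, 1:] = S[np.ix_(P, P)]
            b = np.empty(len(P) + 1)
            b[0] = n * m[child]
            b[1:] = S[P, child]
            if len(P) > 0 and np.linalg.cond(G) > 1e12:
                raise np.linalg.LinAlgError(
                    f"singular parent design for attribute {child} "
                    f"(parents {tuple(P)}) in class {self.classes[k]}"
                )
            theta = np.linalg.solve(G, b)
            rss = max(S[child, child] - theta @ b, 0.0)
            var = max(rss / n, var_floor)
            intercepts[k] = theta[0]
            weights[k] = theta[1:]
            variances[k] = var
            ll += -0.5 * n * math.log(2 * math.pi * var) - 0.5 * rss / var
        return intercepts, weights, variances, ll

    def family_bic(
        self, child: int, parents: tuple[int, ...], var_floor: float = VAR_FLOOR
    ) -> float:
        """BIC contribution of one attribute family: max log-likelihood minus
        (ln N / 2) * free parameters, with C*(|parents| + 2) parameters
        (per-class intercept, weights, variance)."""
        *_, ll = self.family_fit(child, parents, var_floor)
        k = len(self.classes) * (len(parents) + 2)
        return ll - 0.5 * math.log(self.n_total) * k

    def class_family_bic(self) -> float:
        """BIC contribution of the class node (multinomial prior)."""
        n = self.counts
        ll = float(np.sum(n * np.log(n / self.n_total)))
        return ll - 0.5 * math.log(self.n_total) * (len(self.classes) - 1)


# ---------------------------------------------------------------------------
# discrete mode


@dataclass
class Discretizer:
    """Equal-frequency binning fitted on training data, applied to any data."""

    edges: list[np.ndarray]  # inner bin edges per column
    n_bins: int

    @classmethod
    def fit(cls, X: np.ndarray, n_bins: int = 4) -> "Discretizer":
        X = np.asarray(X, dtype=float)
        qs = np.linspace(0, 1, n_bins + 1)[1:-1]
        edges = [np.quantile(X[:, j], qs) for j in range(X.shape[1])]
        return cls(edges, n_bins)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape, dtype=np.int64)
        for j, e in enumerate(self.edges):
            out[:, j] = np.searchsorted(e, X[:, j], side="right")
        return out


class DiscreteSuffStats:
    """Per-class contingency machinery for CPT families on integer data."""

    def __init__(self, X: np.ndarray, y: np.ndarray, cards: np.ndarray | None = None):
        self.X = np.asarray(X, dtype=np.int64)
        if self.X.min() < 0:
            raise ValueError("discrete data must be non-negative integers")
        y = np.asarray(y)
        self.classes, self.counts = np.unique(y, return_counts=True)
        self.n_total = len(y)
        self.n_attributes = self.X.shape[1]
        self.cards = (
            np.asarray(cards, dtype=np.int64)
            if cards is not None
            else self.X.max(axis=0) + 1
        )
        self.class_rows = [np.flatnonzero(y == c) for c in self.classes]

    def family_counts(self, child: int, parents: tuple[int, ...]) -> np.ndarray:
        shape = (len(self.classes), *[int(self.cards[p]) for p in parents], int(self.cards[child]))
        counts = np.zeros(shape)
        for k, rows in enumerate(self.class_rows):
            idx = (np.full(len(rows), k), *[self.X[rows, p] for p in parents], self.X[rows, child])
            np.add.at(counts, idx, 1.0)
        return counts

    def family_fit(
        self, child: int, parents: tuple[int, ...], pseudo_count: float = 0.0
    ) -> tuple[np.ndarray, float]:
        """(CPT, total log-likelihood).  Pure MLE by default; rows with no
        observations become uniform, and zero cells are floored at predict
        time rather than smoothed."""
        counts = self.family_counts(child, parents)
        smoothed = counts + pseudo_count
        totals = smoothed.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = np.where(totals > 0, smoothed / np.where(totals == 0, 1, totals), 1.0 / counts.shape[-1])
        ll = float(np.sum(counts * np.log(np.maximum(cpt, CPT_FLOOR))))
        return cpt, ll

    def family_bic(self, child: int, parents: tuple[int, ...], pseudo_count: float = 0.0) -> float:
        _, ll = self.family_fit(child, parents, pseudo_count)
        k = len(self.classes) * int(np.prod([self.cards[p] for p in parents])) * (
            int(self.cards[child]) - 1
        )
        return ll - 0.5 * math.log(self.n_total) * k

    def class_family_bic(self) -> float:
        n = self.counts
        ll = float(np.sum(n * np.log(n / self.n_total)))
        return ll - 0.5 * math.log(self.n_total) * (len(self.classes) - 1)


def make_suff_stats(X: np.ndarray, y: np.ndarray, mode: str):
    if mode == "continuous":
        return GaussianSuffStats(X, y)
    if mode == "discrete":
        return DiscreteSuffStats(X, y)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# parameter learning and scoring


def fit_mle(
    structure: DAGStructure,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "continuous",
    var_floor: float = VAR_FLOOR,
    pseudo_count: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, list[ConditionalDistribution]]:
    """Maximum-likelihood parameters for ``structure`` on (X, y).

    Returns (class labels, class prior, conditionals).  The prior is the
    empirical class frequency; each attribute's conditional is fitted per
    class given its attribute parents (least squares + residual variance in
    continuous mode, frequency counts in discrete mode).
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    pm = structure.parent_map()
    if mode == "continuous":
        stats = GaussianSuffStats(X, y)
        for i, P in pm.items():
            need = len(P) + 2
            if np.any(counts < need):
                raise ValueError(
                    f"attribute {i} with {len(P)} parents needs >= {need} trials per class"
                )
        conds = []
        for i in range(structure.n_attributes):
            try:
                ic, w, v, _ = stats.family_fit(i, pm[i], var_floor)
            except np.linalg.LinAlgError as e:
                raise ValueError(str(e)) from e
            conds.append(ConditionalDistribution(i, pm[i], intercepts=ic, weights=w, variances=v))
    elif mode == "discrete":
        stats = DiscreteSuffStats(X, y)
        conds = []
        for i in range(structure.n_attributes):
            cpt, _ = stats.family_fit(i, pm[i], pseudo_count)
            conds.append(ConditionalDistribution(i, pm[i], cpt=cpt))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    prior = counts / counts.sum()
    return classes, prior, conds


def bic_score(
    structure: DAGStructure,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "continuous",
    var_floor: float = VAR_FLOOR,
) -> float:
    """Total BIC of a classifier structure: sum of the class-node family and
    every attribute family's (log-likelihood - penalty) terms."""
    stats = make_suff_stats(X, y, mode)
    pm = structure.parent_map()
    total = stats.class_family_bic()
    for i in range(structure.n_attributes):
        if mode == "continuous":
            total += stats.family_bic(i, pm[i], var_floor)
        else:
            total += stats.family_bic(i, pm[i])
    return total


# ---------------------------------------------------------------------------
# hill climbing


@dataclass
class SearchConfig:
    """Hill-climbing settings: parent bound, step bound, CPD mode."""

    max_parents: int = 3
    max_steps: int | None = None  # default 10 * n_attributes
    mode: str = "continuous"
    var_floor: float = VAR_FLOOR
    improvement_tol: float = 1e-9


def hill_climb_augment(
    X: np.ndarray,
    y: np.ndarray,
    max_parents: int = 3,
    max_steps: int | None = None,
    seed: int = 0,
    mode: str = "continuous",
    var_floor: float = VAR_FLOOR,
    improvement_tol: float = 1e-9,
) -> tuple[DAGStructure, ScoreTrace]:
    """Greedy BIC hill climbing over attribute->attribute edges.

    Starts from the naive Bayes skeleton; at each step evaluates every
    admissible insertion, deletion, and reversal of a single attribute
    edge (class edges are immutable), applies the best strictly improving
    one, and stops when none improves the score or ``max_steps`` is
    reached.  Every intermediate structure is acyclic and respects
    ``max_parents``.  Ties are broken by canonical move order
    (add < delete < reverse, then parent id, then child id), so the search
    is deterministic; ``seed`` is accepted for interface stability but
    unused.
    """
    del seed
    stats = make_suff_stats(X, y, mode)
    d = stats.n_attributes
    if d < 2:
        raise ValueError("need at least 2 attributes")
    if max_steps is None:
        max_steps = 10 * d

    parents: dict[int, frozenset[int]] = {i: frozenset() for i in range(d)}
    g = nx.DiGraph()
    g.add_nodes_from(range(d))
    cache: dict[tuple[int, frozenset[int]], float] = {}

    def fam(child: int, ps: frozenset[int]) -> float:
        key = (child, ps)
        if key not in cache:
            try:
                if mode == "continuous":
                    cache[key] = stats.family_bic(child, tuple(sorted(ps)), var_floor)
                else:
                    cache[key] = stats.family_bic(child, tuple(sorted(ps)))
            except np.linalg.LinAlgError:
                cache[key] = -math.inf  # inadmissible (collinear) family
        return cache[key]

    score = stats.class_family_bic() + sum(fam(i, parents[i]) for i in range(d))
    trace = ScoreTrace(initial_score=score)

    for step in range(max_steps):
        desc = {v: nx.descendants(g, v) for v in range(d)}
        best_delta = improvement_tol
        best_move = None

        # additions
        for u in range(d):
            for v in range(d):
                if u == v or g.has_edge(u, v) or len(parents[v]) >= max_parents:
                    continue
                if u in desc[v]:
                    continue  # would create a cycle
                delta = fam(v, parents[v] | {u}) - fam(v, parents[v])
                if delta > best_delta:
                    best_delta, best_move = delta, ("add", u, v)
        # deletions
        for u, v in sorted(g.edges()):
            delta = fam(v, parents[v] - {u}) - fam(v, parents[v])
            if delta > best_delta:
                best_delta, best_move = delta, ("delete", u, v)
        # reversals
        for u, v in sorted(g.edges()):
            if len(parents[u]) >= max_parents:
                continue
            g.remove_edge(u, v)
            creates_cycle = nx.has_path(g, u, v)
            g.add_edge(u, v)
            if creates_cycle:
                continue
            delta = (fam(v, parents[v] - {u}) - fam(v, parents[v])) + (
                fam(u, parents[u] | {v}) - fam(u, parents[u])
            )
            if delta > best_delta:
                best_delta, best_move = delta, ("reverse", u, v)

        if best_move is None:
            break
        kind, u, v = best_move
        before = score
        if kind == "add":
            g.add_edge(u, v)
            parents[v] = parents[v] | {u}
        elif kind == "delete":
            g.remove_edge(u, v)
            parents[v] = parents[v] - {u}
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
            parents[v] = parents[v] - {u}
            parents[u] = parents[u] | {v}
        score = before + best_delta
        trace.records.append(MoveRecord(step, kind, (u, v), before, score))

    structure = DAGStructure(d, tuple(sorted(g.edges())))
    return structure, trace
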