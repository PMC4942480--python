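"""Bayesian-network core: structures, MLE, BIC, hill climbing."""

import math

import numpy as np
import pytest

from bndecode import (
    DAGStructure,
    bic_score,
    empty_structure,
    fit_mle,
    hill_climb_augment,
)
from bndecode.bn import (
    DiscreteSuffStats,
    GaussianSuffStats,
)
from bndecode.synth import (
    GenerativeModel,
    generate_response_dataset,
    generate_voxel_geometry,
)


class TestDAGStructure:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DAGStructure(3, ((0, 1), (1, 2), (2, 0)))

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            DAGStructure(2, ((1, 1),))

    def test_parent_map(self):
        s = DAGStructure(4, ((0, 2), (1, 2), (2, 3)))
        assert s.parent_map() == {0: (), 1: (), 2: (0, 1), 3: (2,)}


class TestFitMLE:
    def test_two_point_gaussian(self):
        """Parentless attribute, class data {1, 3}: mean 2, population var 1."""
        X = np.array([[1.0], [3.0], [10.0], [12.0]])
        y = np.array([0, 0, 1, 1])
        classes, prior, conds = fit_mle(empty_structure(1), X, y)
        np.testing.assert_allclose(prior, [0.5, 0.5])
        assert conds[0].intercepts[0] == pytest.approx(2.0)
        assert conds[0].variances[0] == pytest.approx(1.0)

    def test_exact_linear_dependence(self):
        """Noiseless A2 = 2*A1 within class: weight 2, variance at floor."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        X = np.column_stack([a, 2 * a])
        y = np.repeat([0, 1], 20)
        s = DAGStructure(2, ((0, 1),))
        _, _, conds = fit_mle(s, X, y, var_floor=1e-8)
        assert conds[1].weights[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert conds[1].variances[0] == pytest.approx(1e-8)

    def test_balanced_priors(self):
        y = np.repeat(np.arange(10), 7)
        X = np.random.default_rng(1).normal(size=(70, 2))
        _, prior, _ = fit_mle(empty_structure(2), X, y)
        np.testing.assert_allclose(prior, 0.1)

    def test_empty_class_structure_demand(self):
        """Too few trials per class for the parent count raises."""
        X = np.random.default_rng(2).normal(size=(6, 4))
        y = np.repeat([0, 1], 3)
        s = DAGStructure(4, ((0, 3), (1, 3), (2, 3)))
        with pytest.raises(ValueError, match="trials per class"):
            fit_mle(s, X, y)

    def test_consistency_recovers_generating_parameters(self):
        """MLE converges to the planted intercepts/weights/variances."""
        geo = generate_voxel_geometry(3, {"BA18": 3}, seed=0)
        model = GenerativeModel(
            n_classes=2,
            class_means=np.array([[0.5, -1.0, 2.0], [-0.5, 1.0, 0.0]]),
            edges=((0, 1), (1, 2)),
            edge_weights={(0, 1): 1.5, (1, 2): -0.8},
            noise_sd=1.0,
        )
        tm = generate_response_dataset(model, 5000, geo, seed=3)
        s = DAGStructure(3, model.edges)
        _, _, conds = fit_mle(s, tm.values, tm.labels)
        for c in range(2):
            assert conds[1].weights[c, 0] == pytest.approx(1.5, abs=0.05)
            assert conds[2].weights[c, 0] == pytest.approx(-0.8, abs=0.05)
            assert conds[1].intercepts[c] == pytest.approx(model.class_means[c, 1], abs=0.05)
            assert conds[1].variances[c] == pytest.approx(1.0, abs=0.05)


class TestBIC:
    def test_closed_form_single_gaussian_family(self):
        """Data {-1, +1}: ll = -ln(2*pi) - 1, 2 parameters, penalty ln 2."""
        stats = GaussianSuffStats(np.array([[-1.0], [1.0]]), np.array([0, 0]))
        got = stats.family_bic(0, ())
        expected = (-math.log(2 * math.pi) - 1.0) - math.log(2)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(-3.5310, abs=5e-4)

    def test_duplicating_data_doubles_ll_but_not_penalty(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([0, 0])
        s1 = GaussianSuffStats(X, y).family_bic(0, ())
        s2 = GaussianSuffStats(np.vstack([X, X]), np.tile(y, 2)).family_bic(0, ())
        ll = -math.log(2 * math.pi) - 1.0
        assert s2 == pytest.approx(2 * ll - math.log(4), abs=1e-10)
        assert s1 == pytest.approx(ll - math.log(2), abs=1e-10)

    def test_structure_score_is_sum_of_family_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 4))
        y = np.repeat([0, 1, 2], 20)
        s = DAGStructure(4, ((0, 1), (2, 3)))
        stats = GaussianSuffStats(X, y)
        total = stats.class_family_bic() + sum(
            stats.family_bic(i, s.parent_map()[i]) for i in range(4)
        )
        assert bic_score(s, X, y) == pytest.approx(total, abs=1e-10)

    def test_decomposability_incremental_equals_full(self):
        """After a sequence of edge changes, rescoring only touched families
        reproduces the from-scratch score."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 5))
        y = np.repeat([0, 1], 40)
        stats = GaussianSuffStats(X, y)
        structures = [
            DAGStructure(5),
            DAGStructure(5, ((0, 1),)),
            DAGStructure(5, ((0, 1), (3, 4))),
            DAGStructure(5, ((3, 4),)),
        ]
        prev = bic_score(structures[0], X, y)
        for s_prev, s_next in zip(structures, structures[1:]):
            pm_prev, pm_next = s_prev.parent_map(), s_next.parent_map()
            delta = sum(
                stats.family_bic(i, pm_next[i]) - stats.family_bic(i, pm_prev[i])
                for i in range(5)
                if pm_next[i] != pm_prev[i]
            )
            prev = prev + delta
            assert prev == pytest.approx(bic_score(s_next, X, y), abs=1e-8)


class TestDiscreteMode:
    def test_likelihood_matches_joint_enumeration(self):
        """Factorized log-likelihood equals brute-force joint enumeration on
        binary attributes (independent oracle: build the full joint table)."""
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(100, 4))
        y = rng.integers(0, 2, size=100)
        s = DAGStructure(4, ((0, 1), (1, 2)))
        stats = DiscreteSuffStats(X, y)
        pm = s.parent_map()
        ll_fact = sum(stats.family_fit(i, pm[i])[1] for i in range(4))
        ll_class = float(np.sum(stats.counts * np.log(stats.counts / stats.n_total)))

        # oracle: enumerate P(c, x) over all 2*16 cells from empirical CPTs
        def cpt_prob(i, parents, xi, parent_vals, c):
            rows = y == stats.classes[c]
            for p, v in zip(parents, parent_vals):
                rows = rows & (X[:, p] == v)
            denom = rows.sum()
            return (rows & (X[:, i] == xi)).sum() / denom if denom else 0.25

        ll_joint = 0.0
        from itertools import product
        for c, *xs in product(range(2), *[range(2)] * 4):
            n_cell = int(np.sum((y == stats.classes[c])
                                & np.all(X == np.array(xs), axis=1)))
            if n_cell == 0:
                continue
            p = stats.counts[c] / stats.n_total
            for i in range(4):
                p *= cpt_prob(i, pm[i], xs[i], [xs[q] for q in pm[i]], c)
            ll_joint += n_cell * math.log(p)
        assert ll_fact + ll_class == pytest.approx(ll_joint, abs=1e-10)


class TestHillClimb:
    def test_null_data_yields_no_edges(self, independent_dataset):
        tm, _ = independent_dataset
        X = tm.values[:, :10]
        s, trace = hill_climb_augment(X, tm.labels)
        assert s.edges == ()

    def test_planted_edge_recovered_as_adjacency(self):
        geo = generate_voxel_geometry(6, {"BA18": 6}, seed=0)
        model = GenerativeModel(
            n_classes=10,
            class_means=np.random.default_rng(7).normal(size=(10, 6)),
            edges=((1, 2),),
            edge_weights={(1, 2): 1.5},
            noise_sd=1.0,
        )
        tm = generate_response_dataset(model, 200, geo, seed=8)
        s, _ = hill_climb_augment(tm.values, tm.labels)
        assert frozenset((1, 2)) in s.adjacencies()

    def test_score_trace_monotone_and_consistent(self, planted_dataset):
        tm, _ = planted_dataset
        s, trace = hill_climb_augment(tm.values[:, :12], tm.labels)
        scores = trace.scores
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        # final incremental score equals a full recomputation
        assert scores[-1] == pytest.approx(
            bic_score(DAGStructure(12, s.edges), tm.values[:, :12], tm.labels),
            abs=1e-8,
        )

    def test_max_parents_respected(self, planted_dataset):
        tm, _ = planted_dataset
        s, _ = hill_climb_augment(tm.values[:, :12], tm.labels, max_parents=1)
        children = [c for _, c in s.edges]
        assert len(children) == len(set(children))

    def test_acyclic_after_search(self, planted_dataset):
        tm, _ = planted_dataset
        s, _ = hill_climb_augment(tm.values[:, :15], tm.labels)
        DAGStructure(15, s.edges)  # __post_init__ validates acyclicity

    def test_deterministic(self, planted_dataset):
        tm, _ = planted_dataset
        s1, _ = hill_climb_augment(tm.values[:, :10], tm.labels)
        s2, _ = hill_climb_augment(tm.values[:, :10], tm.labels)
        assert s1.edges == s2.edges
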