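"""Naive Bayes and augmented naive Bayes classifiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bndecode import (
    accuracy,
    chance_level,
    fit_augmented_nb,
    fit_naive_bayes,
    generate_coupling_contrast_dataset,
    predict,
    predict_posterior,
)
from bndecode.bn import DAGStructure, SearchConfig, fit_mle
from bndecode.classify import BNClassifierModel, _log_likelihood_matrix


@pytest.fixture(scope="module")
def random_model():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(120, 5)) + rng.integers(0, 3, size=(120, 1))
    y = rng.integers(0, 3, size=120)
    return X, y, fit_naive_bayes(X, y)


class TestNaiveBayes:
    def test_structure_has_no_augmenting_edges(self, random_model):
        _, _, model = random_model
        assert model.augmenting_edges == ()

    def test_symmetric_two_class_posterior(self):
        """Means 0 and 4, equal sd and priors: posterior at x=2 is (.5, .5)."""
        X = np.array([[-1.0], [1.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_naive_bayes(X, y)
        post = predict_posterior(model, np.array([2.0]))
        np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)

    def test_matches_sklearn_gaussian_nb(self, random_model):
        """Independent oracle: scikit-learn's GaussianNB (same MLE family)."""
        from sklearn.naive_bayes import GaussianNB

        X, y, model = random_model
        rng = np.random.default_rng(1)
        X_test = rng.normal(size=(200, 5)) + rng.integers(0, 3, size=(200, 1))
        ours = predict(model, X_test)
        ref = GaussianNB(var_smoothing=1e-12).fit(X, y).predict(X_test)
        assert np.mean(ours == ref) == 1.0

    def test_posterior_rows_sum_to_one(self, random_model):
        X, _, model = random_model
        post = predict_posterior(model, X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_uninformative_likelihood_gives_uniform_posterior(self):
        """Identical per-class conditionals, uniform prior: every entry 1/C."""
        base = fit_naive_bayes(
            np.random.default_rng(2).normal(size=(40, 3)), np.repeat(np.arange(10), 4)
        )
        for cond in base.conditionals:
            cond.intercepts[:] = 0.0
            cond.variances[:] = 1.0
        post = predict_posterior(base, np.array([0.3, -0.2, 1.0]))
        np.testing.assert_allclose(post, 0.1, atol=1e-12)

    def test_non_finite_input_rejected(self, random_model):
        _, _, model = random_model
        with pytest.raises(ValueError, match="non-finite"):
            predict_posterior(model, np.array([np.nan, 0, 0, 0, 0]))

    def test_tie_broken_by_smallest_label(self):
        base = fit_naive_bayes(
            np.random.default_rng(3).normal(size=(20, 2)), np.repeat([3, 5, 7, 9], 5)
        )
        for cond in base.conditionals:
            cond.intercepts[:] = 0.0
            cond.variances[:] = 1.0
        base.class_prior[:] = 0.25
        assert predict(base, np.array([[0.0, 0.0]]))[0] == 3

    def test_log_domain_survives_extreme_values(self, random_model):
        _, _, model = random_model
        post = predict_posterior(model, np.full((1, 5), 100.0))
        assert np.all(np.isfinite(post))
        np.testing.assert_allclose(post.sum(), 1.0, atol=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_posterior_invariant_to_common_likelihood_factor(self, seed):
        """Scaling all class likelihoods by exp(g(x)) leaves posteriors
        unchanged: adding a constant to every class's log-joint is a no-op."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 3))
        y = np.repeat([0, 1, 2], 10)
        model = fit_naive_bayes(X, y)
        logp = _log_likelihood_matrix(model, X)
        shifted = logp + rng.normal(size=(30, 1))  # common per-trial factor
        from scipy.special import logsumexp

        p1 = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        p2 = np.exp(shifted - logsumexp(shifted, axis=1, keepdims=True))
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestAugmentedNB:
    def test_empty_augmentation_equals_naive_bayes(self, random_model):
        """When the search returns no edges the two classifiers coincide."""
        X, y, nb = random_model
        anb = fit_augmented_nb(X, y, search=SearchConfig(max_steps=0))
        assert anb.augmenting_edges == ()
        np.testing.assert_allclose(
            predict_posterior(anb, X), predict_posterior(nb, X), atol=1e-12
        )

    def test_class_is_parent_of_every_attribute(self, random_model):
        X, y, _ = random_model
        anb = fit_augmented_nb(X, y)
        # per-class parameters exist for every attribute: the class edge is
        # implicit and immutable
        assert all(c.intercepts.shape == (3,) for c in anb.conditionals)

    def test_anb_decodes_coupling_sign_where_nb_is_blind(self):
        """Classes differing only in dependency sign: identical marginals
        leave naive Bayes at chance; the augmented classifier exceeds 0.8."""
        tm, _ = generate_coupling_contrast_dataset(
            n_pairs=4, n_per_class=500, weight=1.5, seed=0
        )
        half = np.concatenate([np.arange(0, 250), np.arange(500, 750)])
        rest = np.setdiff1d(np.arange(1000), half)
        nb = fit_naive_bayes(tm.values[half], tm.labels[half])
        anb = fit_augmented_nb(tm.values[half], tm.labels[half])
        nb_acc = accuracy(tm.labels[rest], predict(nb, tm.values[rest]))
        anb_acc = accuracy(tm.labels[rest], predict(anb, tm.values[rest]))
        assert abs(nb_acc - chance_level(2)) < 0.1
        assert anb_acc > 0.8

    def test_discrete_mode_roundtrip(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=200)
        X = rng.normal(size=(200, 3)) + 2.0 * y[:, None]
        model = fit_naive_bayes(X, y, mode="discrete")
        post = predict_posterior(model, X)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert accuracy(y, predict(model, X)) > 0.6


class TestDiscretePosteriorOracle:
    def test_posterior_equals_joint_enumeration(self):
        """2 classes, 3 binary attributes with an edge: the posterior matches
        a brute-force enumeration of the full joint table."""
        rng = np.random.default_rng(5)
        X = rng.integers(0, 2, size=(150, 3)).astype(float)
        y = rng.integers(0, 2, size=150)
        s = DAGStructure(3, ((0, 1),))
        classes, prior, conds = fit_mle(s, X.astype(int), y, mode="discrete")
        model = BNClassifierModel(s, classes, prior, conds, mode="discrete")

        from itertools import product

        for xs in product(range(2), repeat=3):
            x = np.array(xs, dtype=float)
            post = predict_posterior(model, x)
            joint = np.empty(2)
            for c in range(2):
                p = prior[c]
                p *= conds[0].cpt[c, xs[0]]
                p *= conds[1].cpt[c, xs[0], xs[1]]
                p *= conds[2].cpt[c, xs[2]]
                joint[c] = p
            np.testing.assert_allclose(post, joint / joint.sum(), atol=1e-10)


class TestPredictAndAccuracy:
    def test_perfect_predictions_give_accuracy_one(self):
        y = np.array([0, 1, 2, 1])
        assert accuracy(y, y.copy()) == 1.0

    def test_permuted_labels_hit_chance(self):
        """Random balanced 10-class guessing sits at ~10% accuracy."""
        rng = np.random.default_rng(6)
        y = np.repeat(np.arange(10), 100)
        accs = [np.mean(rng.permutation(y) == y) for _ in range(50)]
        assert np.mean(accs) == pytest.approx(chance_level(10), abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            accuracy(np.zeros(3), np.zeros(4))


def test_discrete_mode_search_recovers_planted_coupling():
    """The discrete (CPT) path of the structure search also finds a strong
    planted dependency."""
    from bndecode import generate_coupling_contrast_dataset

    tm, _ = generate_coupling_contrast_dataset(n_pairs=1, n_per_class=500,
                                               weight=2.0, seed=2)
    anb = fit_augmented_nb(tm.values, tm.labels,
                           search=SearchConfig(mode="discrete"))
    assert frozenset((0, 1)) in anb.structure.adjacencies()
    assert accuracy(tm.labels, predict(anb, tm.values)) > 0.7
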