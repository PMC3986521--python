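"""Gaussian mixtures: likelihood closed forms, BIC, EM behavior, recovery."""

import numpy as np
import pytest

from effortdecode import bic, fit_class_gmm, log_likelihood
from effortdecode.errors import FitError, NumericError, UsageError
from effortdecode.gmm import (ClassGMM, GaussianComponent, GMMClassifier,
                              n_free_parameters)


def unit_gauss_1d():
    return ClassGMM([GaussianComponent(1.0, np.zeros(1), np.eye(1))])


class TestLogLikelihood:
    def test_standard_normal_at_origin(self):
        ll = log_likelihood(unit_gauss_1d(), np.zeros((1, 1)))
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_additivity_under_row_duplication(self):
        X = np.random.default_rng(0).normal(size=(50, 1))
        ll = log_likelihood(unit_gauss_1d(), X)
        assert log_likelihood(unit_gauss_1d(), np.vstack([X, X])) == \
            pytest.approx(2 * ll, rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 0.2, 0.9])
    def test_identical_components_collapse(self, alpha):
        split = ClassGMM([
            GaussianComponent(alpha, np.zeros(1), np.eye(1)),
            GaussianComponent(1 - alpha, np.zeros(1), np.eye(1))])
        X = np.random.default_rng(1).normal(size=(30, 1))
        assert log_likelihood(split, X) == \
            pytest.approx(log_likelihood(unit_gauss_1d(), X), rel=1e-12)

    def test_matches_sklearn_oracle(self):
        """Same fixed parameters evaluated through sklearn's mixture."""
        from sklearn.mixture import GaussianMixture
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 3))
        means = np.array([[0.0, 0, 0], [2.0, 1, -1]])
        covs = np.array([np.eye(3), np.diag([2.0, 0.5, 1.0])])
        weights = np.array([0.3, 0.7])
        ours = ClassGMM([GaussianComponent(w, m, c)
                         for w, m, c in zip(weights, means, covs)])
        sk = GaussianMixture(n_components=2, covariance_type="full")
        sk.weights_, sk.means_, sk.covariances_ = weights, means, covs
        sk.precisions_cholesky_ = np.array(
            [np.linalg.cholesky(np.linalg.inv(c)).T for c in covs])
        assert log_likelihood(ours, X) == \
            pytest.approx(float(sk.score_samples(X).sum()), rel=1e-10)


class TestBIC:
    def test_as_printed_value(self):
        # zero log-likelihood contribution: evaluate the penalty term alone
        gmm = unit_gauss_1d()
        X = np.zeros((10, 1))
        expected = -2 * log_likelihood(gmm, X) + 2 * np.log(10)
        assert bic(gmm, X, mode="as-printed") == pytest.approx(expected)
        assert 2 * np.log(10) == pytest.approx(4.60517, abs=1e-5)

    def test_standard_penalty_grows_with_k(self):
        assert n_free_parameters(2, 3) > n_free_parameters(1, 3)
        split = ClassGMM([
            GaussianComponent(0.5, np.zeros(1), np.eye(1)),
            GaussianComponent(0.5, np.zeros(1), np.eye(1))])
        X = np.random.default_rng(3).normal(size=(100, 1))
        # identical likelihood, so the difference is pure penalty
        assert bic(split, X) > bic(unit_gauss_1d(), X)

    def test_selects_one_component_on_unit_gaussian(self):
        X = np.random.default_rng(4).normal(size=(1000, 1))
        g = fit_class_gmm(X, K_max=5, seed=0)
        assert g.K == 1
        # the brute-force search table agrees
        assert min(g.selection, key=lambda t: t[2])[0] == 1

    def test_too_few_samples(self):
        with pytest.raises(UsageError):
            bic(unit_gauss_1d(), np.zeros((1, 1)))


class TestFitClassGMM:
    def test_recovers_two_separated_components(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal([-5, -5], 1.0, size=(1000, 2)),
                       rng.normal([5, 5], 1.0, size=(1000, 2))])
        gmm = fit_class_gmm(X, K_max=5, seed=1)
        assert gmm.K == 2
        found = sorted(c.mean.tolist() for c in gmm.components)
        assert np.allclose(found[0], [-5, -5], atol=0.1)
        assert np.allclose(found[1], [5, 5], atol=0.1)

    def test_single_gaussian_selects_k1_across_seeds(self):
        hits = 0
        for seed in range(10):
            X = np.random.default_rng(100 + seed).normal(size=(500, 2))
            if fit_class_gmm(X, K_max=4, seed=seed).K == 1:
                hits += 1
        assert hits >= 8

    def test_k1_equals_closed_form(self):
        X = np.random.default_rng(6).normal(2.0, 3.0, size=(400, 2))
        gmm = fit_class_gmm(X, K_max=1, seed=0)
        comp = gmm.components[0]
        assert np.allclose(comp.mean, X.mean(axis=0), atol=1e-8)
        assert np.allclose(comp.cov, np.cov(X.T, ddof=0), atol=1e-8)

    def test_identical_points_degenerate(self):
        with pytest.raises(NumericError):
            fit_class_gmm(np.ones((50, 2)), K_max=2, seed=0)

    def test_deterministic_for_fixed_seed(self):
        X = np.random.default_rng(7).normal(size=(300, 2))
        a = fit_class_gmm(X, K_max=3, seed=5)
        b = fit_class_gmm(X, K_max=3, seed=5)
        assert a.K == b.K
        for ca, cb in zip(a.components, b.components):
            assert np.array_equal(ca.mean, cb.mean)
            assert np.array_equal(ca.cov, cb.cov)

    def test_greedy_insertion_variant_runs(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(-4, 1, size=(300, 1)),
                       rng.normal(4, 1, size=(300, 1))])
        gmm = fit_class_gmm(X, K_max=3, seed=0, init="greedy")
        assert gmm.K == 2

    def test_mean_recovery_improves_with_n(self):
        """Bias of recovered means shrinks as the sample grows."""
        errs = []
        for n in (200, 2000):
            rng = np.random.default_rng(9)
            X = np.vstack([rng.normal(-3, 1, size=(n, 1)),
                           rng.normal(3, 1, size=(n, 1))])
            gmm = fit_class_gmm(X, K_max=2, seed=0)
            means = sorted(c.mean[0] for c in gmm.components)
            errs.append(abs(means[0] + 3) + abs(means[1] - 3))
        assert errs[1] < errs[0] + 0.05


class TestClassifier:
    def test_separable_training_accuracy(self, separable_fm):
        clf = GMMClassifier.fit(separable_fm.X, separable_fm.y, r=2, k_nn=7,
                                K_max=3, seed=0)
        acc = np.mean(clf.predict(separable_fm.X) == separable_fm.y)
        assert acc >= 0.99

    def test_posterior_rows_sum_to_one(self, separable_fm):
        clf = GMMClassifier.fit(separable_fm.X, separable_fm.y, r=2, k_nn=7,
                                K_max=2, seed=0)
        post = clf.posterior(separable_fm.X[:25])
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(FitError):
            GMMClassifier.fit(X, np.repeat("only", 50), r=2)

    def test_point_at_class_mean_wins(self):
        a = ClassGMM([GaussianComponent(1.0, np.zeros(2), np.eye(2))], "a")
        b = ClassGMM([GaussianComponent(1.0, np.full(2, 50.0), np.eye(2))], "b")
        clf = GMMClassifier(models={"a": a, "b": b}, lfda=None)
        post = clf.posterior(np.zeros((1, 2)))
        assert clf.predict(np.zeros((1, 2)))[0] == "a"
        assert post[0, clf.class_labels.index("a")] > 0.99

    def test_tie_breaks_lexicographically(self):
        same = lambda lab: ClassGMM(
            [GaussianComponent(1.0, np.zeros(2), np.eye(2))], lab)
        clf = GMMClassifier(models={"b": same("b"), "a": same("a")}, lfda=None)
        post = clf.posterior(np.zeros((1, 2)))
        assert np.allclose(post, 0.5)
        assert clf.predict(np.zeros((1, 2)))[0] == "a"

    def test_save_load_roundtrip(self, tmp_path, separable_fm):
        clf = GMMClassifier.fit(separable_fm.X, separable_fm.y, r=2, k_nn=7,
                                K_max=2, seed=0)
        clf.save(tmp_path / "clf.json")
        back = GMMClassifier.load(tmp_path / "clf.json")
        X = separable_fm.X[:40]
        assert np.array_equal(back.predict(X), clf.predict(X))
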