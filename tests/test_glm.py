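"""Bernoulli GLM: likelihood, gradients, MAP fitting, cross-validation."""

import numpy as np
import pytest
from scipy.special import expit

from tvrf import (PriorSpec, ReceptiveField, bernoulli_ll,
                  cv_select_hyperparams, fit_map, logistic,
                  penalized_objective)


def _rf(k):
    k = np.asarray(k, dtype=float)
    return ReceptiveField(k=k, b=0.0, n_channels=1, n_lags=k.size, dt_s=1.0)


class TestLogistic:
    def test_midpoint(self):
        assert logistic(0.0) == 0.5

    @pytest.mark.parametrize("z", [1.0, 10.0])
    def test_symmetry(self, z):
        assert logistic(-z) == pytest.approx(1.0 - logistic(z), abs=1e-15)

    def test_extreme_underflow_safe(self):
        v = logistic(-745.0)
        assert np.isfinite(v) and v > 0
        assert logistic(745.0) == pytest.approx(1.0)


class TestBernoulliLL:
    def test_single_spike_at_zero(self):
        assert bernoulli_ll(np.array([1.0]), np.array([0.0])) == \
            pytest.approx(-np.log(2.0))

    def test_saturated_predictions(self):
        ll = bernoulli_ll(np.array([1.0, 0.0]), np.array([10.0, -10.0]))
        assert ll == pytest.approx(-2.0 * np.log1p(np.exp(-10.0)), rel=1e-9)
        assert ll == pytest.approx(-9.08e-5, rel=1e-2)

    def test_all_zero_response_zero_predictor(self):
        N = 37
        assert bernoulli_ll(np.zeros(N), np.zeros(N)) == \
            pytest.approx(-N * np.log(2.0))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_ll(np.array([0.5]), np.array([0.0]))


class TestPenalizedObjective:
    def test_unpenalized_equals_likelihood(self, rng):
        S = rng.standard_normal((10, 6))
        r = (rng.random(10) < 0.5).astype(float)
        k, b = rng.standard_normal(6), 0.3
        prior = PriorSpec("zero_mean", alpha=0.0)
        val, _ = penalized_objective(k, b, S, r, prior)
        assert val == pytest.approx(bernoulli_ll(r, S @ k + b))

    def test_penalty_vanishes_at_prior_mean(self, rng):
        S = rng.standard_normal((10, 6))
        r = (rng.random(10) < 0.5).astype(float)
        k0 = rng.standard_normal(6)
        prior = PriorSpec("adaptive", beta=50.0, prior_mean=_rf(k0))
        val, _ = penalized_objective(k0, 0.1, S, r, prior)
        assert val == pytest.approx(bernoulli_ll(r, S @ k0 + 0.1))

    def test_gradient_matches_finite_differences(self, rng):
        S = rng.standard_normal((10, 6))
        r = (rng.random(10) < 0.4).astype(float)
        k = 0.5 * rng.standard_normal(6)
        b = -0.2
        k0 = rng.standard_normal(6)
        prior = PriorSpec("mixed", alpha=1.3, beta=2.1, prior_mean=_rf(k0))
        _, (gk, gb) = penalized_objective(k, b, S, r, prior)
        h = 1e-6
        for i in range(6):
            e = np.zeros(6); e[i] = h
            vp, _ = penalized_objective(k + e, b, S, r, prior)
            vm, _ = penalized_objective(k - e, b, S, r, prior)
            assert gk[i] == pytest.approx((vp - vm) / (2 * h), rel=1e-5,
                                          abs=1e-8)
        vp, _ = penalized_objective(k, b + h, S, r, prior)
        vm, _ = penalized_objective(k, b - h, S, r, prior)
        assert gb == pytest.approx((vp - vm) / (2 * h), rel=1e-5)

    def test_hessian_negative_semidefinite(self, rng):
        """The penalized log-likelihood is concave in (k, b)."""
        S = rng.standard_normal((15, 4))
        prior = PriorSpec("zero_mean", alpha=0.7)
        for _ in range(3):
            k = rng.standard_normal(4)
            b = rng.standard_normal()
            z = S @ k + b
            w = expit(z) * (1 - expit(z))
            X = np.hstack([S, np.ones((15, 1))])
            H = -(X.T * w) @ X
            H[:4, :4] -= prior.alpha * np.eye(4)
            assert np.linalg.eigvalsh(H).max() <= 1e-10


def _grid_zoom_oracle(S, r, prior, lo=-5.0, hi=5.0, levels=6, n=15):
    """Dense brute-force maximization over (k1, k2, b) by iterative zoom."""
    def obj(k1, k2, b):
        val, _ = penalized_objective(np.array([k1, k2]), b, S, r, prior)
        return val
    centers = np.zeros(3)
    half = hi - lo
    best = None
    for _ in range(levels):
        axes = [np.linspace(c - half / 2, c + half / 2, n) for c in centers]
        vals = np.array([[[obj(a, b_, c) for c in axes[2]]
                          for b_ in axes[1]] for a in axes[0]])
        i, j, k = np.unravel_index(np.argmax(vals), vals.shape)
        centers = np.array([axes[0][i], axes[1][j], axes[2][k]])
        best = vals[i, j, k]
        half *= 2.5 / n
    return best, centers


class TestFitMap:
    def test_prior_dominated_limit(self, rng):
        S = rng.standard_normal((30, 5))
        r = (rng.random(30) < 0.3).astype(float)
        k0 = rng.standard_normal(5)
        prior = PriorSpec("adaptive", beta=1e8, prior_mean=_rf(k0))
        fit = fit_map(S, r, prior)
        assert np.linalg.norm(fit.rf.k - k0) <= 1e-3 * np.linalg.norm(k0)

    def test_matches_grid_search_oracle(self, rng):
        S = rng.standard_normal((8, 2))
        r = np.array([1.0, 0, 0, 1, 0, 1, 0, 0])
        prior = PriorSpec("zero_mean", alpha=0.5)
        fit = fit_map(S, r, prior)
        best, theta = _grid_zoom_oracle(S, r, prior)
        assert fit.objective_value == pytest.approx(best, abs=1e-6)

    def test_solution_independent_of_initialization(self, rng):
        S = rng.standard_normal((40, 6))
        r = (rng.random(40) < 0.4).astype(float)
        k0 = rng.standard_normal(6)
        prior = PriorSpec("mixed", alpha=1.0, beta=2.0, prior_mean=_rf(k0))
        f1 = fit_map(S, r, prior, init=np.zeros(7))
        f2 = fit_map(S, r, prior, init=np.append(k0, 0.0))
        np.testing.assert_allclose(
            np.append(f1.rf.k, f1.rf.b), np.append(f2.rf.k, f2.rf.b),
            atol=1e-6)

    def test_approaches_unpenalized_logistic_regression(self, rng):
        """With vanishing penalty and abundant data the MAP solution
        matches an independent logistic-regression solver."""
        from sklearn.linear_model import LogisticRegression
        S = rng.standard_normal((4000, 4))
        k_true = np.array([1.0, -0.5, 0.3, 0.8])
        r = (rng.random(4000) < expit(S @ k_true - 1.0)).astype(float)
        fit = fit_map(S, r, PriorSpec("zero_mean", alpha=1e-8), tol=1e-9)
        sk = LogisticRegression(C=np.inf, tol=1e-10, max_iter=2000)
        sk.fit(S, r)
        np.testing.assert_allclose(fit.rf.k, sk.coef_.ravel(), atol=1e-4)
        assert fit.rf.b == pytest.approx(float(sk.intercept_[0]), abs=1e-4)

    def test_separable_data_guard(self):
        S = np.array([[1.0], [2.0], [-1.0], [-2.0]])
        r = np.array([1.0, 1.0, 0.0, 0.0])
        with pytest.raises(RuntimeError, match="separable"):
            fit_map(S, r, PriorSpec("zero_mean", alpha=0.0), tol=0.0,
                    max_iter=5000)


class TestCvSelect:
    def _data(self, rng, n=100, d=4, p=0.2):
        S = rng.standard_normal((n, d))
        r = (rng.random(n) < p).astype(float)
        return S, r

    def test_single_point_grid(self, rng):
        S, r = self._data(rng)
        cv = cv_select_hyperparams(S, r, None, grid=[(3.0, 0.0)], seed=0)
        assert cv.selected == (3.0, 0.0)

    def test_folds_stratified_by_spike_presence(self, rng):
        S = rng.standard_normal((100, 3))
        r = np.zeros(100); r[:20] = 1.0
        r = r[rng.permutation(100)]
        cv = cv_select_hyperparams(S, r, None, grid=[(1.0, 0.0)], seed=1)
        for j in range(5):
            fold_spikes = r[cv.fold_assignments == j].sum()
            assert abs(fold_spikes - 4) <= 1

    def test_selected_is_argmax_of_mean_heldout_ll(self, rng):
        S, r = self._data(rng, n=200)
        grid = [(0.1, 0.0), (10.0, 0.0), (1000.0, 0.0)]
        cv = cv_select_hyperparams(S, r, None, grid=grid, seed=2)
        assert cv.selected in grid
        best = cv.mean_heldout_ll.max()
        i = grid.index(cv.selected)
        assert cv.mean_heldout_ll[i] == pytest.approx(best)
        assert best >= cv.mean_heldout_ll.min()

    def test_degenerate_response_rejected(self, rng):
        S = rng.standard_normal((50, 3))
        with pytest.raises(ValueError, match="degenerate"):
            cv_select_hyperparams(S, np.zeros(50), None, grid=[(1.0, 0.0)])

    def test_data_from_prior_mean_selects_strong_beta(self):
        """When the data really come from the prior-mean filter, CV
        prefers trusting the prior (large beta) most of the time."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(500 + seed)
            D = 12
            k0 = rng.standard_normal(D)
            k0 *= 1.5 / np.linalg.norm(k0)
            S = rng.standard_normal((400, D))
            r = (rng.random(400) < expit(S @ k0 - 2.0)).astype(float)
            cv = cv_select_hyperparams(
                S, r, _rf(k0), grid=[(0.0, 0.1), (0.0, 1000.0)], seed=seed)
            wins += cv.selected == (0.0, 1000.0)
        assert wins >= 0.8 * n_rep
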