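"""Closed-form linear-Gaussian estimators against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tvrf import (adaptive_estimate, mixed_estimate, ml_estimate,
                  rf_correlation, ridge_estimate, simulate_linear_gaussian)


def qp_oracle(S, r, lam_a, lam_b, k_prior):
    """Augmented least squares for ||r-Sk||^2 + la||k||^2 + lb||k-k0||^2."""
    D = S.shape[1]
    A = np.vstack([S, np.sqrt(lam_a) * np.eye(D), np.sqrt(lam_b) * np.eye(D)])
    y = np.concatenate([r, np.zeros(D), np.sqrt(lam_b) * k_prior])
    return np.linalg.lstsq(A, y, rcond=None)[0]


class TestMlEstimate:
    def test_identity_design(self):
        np.testing.assert_allclose(
            ml_estimate(np.eye(2), np.array([3.0, -1.0])).k_hat, [3.0, -1.0])

    def test_noise_free_recovery(self):
        S = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        k = np.array([2.0, -1.0])
        np.testing.assert_allclose(ml_estimate(S, S @ k).k_hat, k,
                                   atol=1e-12)

    def test_matches_pseudoinverse_oracle(self, rng):
        S = rng.standard_normal((50, 8))
        k_true = rng.standard_normal(8)
        r = simulate_linear_gaussian(S, k_true, sigma=0.1, seed=5)
        k_hat = ml_estimate(S, r).k_hat
        np.testing.assert_allclose(k_hat, np.linalg.pinv(S) @ r, atol=1e-10)

    def test_rank_deficient_errors(self):
        S = np.array([[1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            ml_estimate(S, np.array([1.0, 2.0]))


class TestRidgeEstimate:
    def test_alpha_zero_is_ml(self, rng):
        S = rng.standard_normal((30, 5))
        r = rng.standard_normal(30)
        np.testing.assert_allclose(ridge_estimate(S, r, 0.0).k_hat,
                                   ml_estimate(S, r).k_hat, atol=1e-12)

    def test_hand_example(self):
        np.testing.assert_allclose(
            ridge_estimate(np.eye(2), np.array([1.0, 1.0]), 1.0).k_hat,
            [0.5, 0.5])

    def test_large_alpha_approaches_sta(self, rng):
        """alpha * k_hat -> S'r (the spike-triggered average direction)."""
        S = rng.standard_normal((40, 6))
        r = rng.standard_normal(40)
        alpha = 1e12
        sta = S.T @ r
        np.testing.assert_allclose(alpha * ridge_estimate(S, r, alpha).k_hat,
                                   sta, rtol=1e-3)

    @given(st.integers(min_value=0, max_value=6))
    def test_monotone_shrinkage(self, i):
        rng = np.random.default_rng(77)
        S = rng.standard_normal((25, 5))
        r = rng.standard_normal(25)
        alphas = np.logspace(-2, 4, 8)
        norms = [np.linalg.norm(ridge_estimate(S, r, a).k_hat)
                 for a in alphas]
        assert norms[i] >= norms[i + 1] - 1e-12


class TestAdaptiveEstimate:
    def test_beta_zero_is_ml(self, rng):
        S = rng.standard_normal((30, 5))
        r = rng.standard_normal(30)
        k0 = rng.standard_normal(5)
        np.testing.assert_allclose(adaptive_estimate(S, r, k0, 0.0).k_hat,
                                   ml_estimate(S, r).k_hat, atol=1e-12)

    def test_hand_example(self):
        k = adaptive_estimate(np.eye(2), np.zeros(2),
                              np.array([2.0, 2.0]), 1.0).k_hat
        np.testing.assert_allclose(k, [1.0, 1.0])

    def test_prior_dominated_limit(self, rng):
        S = rng.standard_normal((20, 4))
        r = rng.standard_normal(20)
        k0 = rng.standard_normal(4)
        k = adaptive_estimate(S, r, k0, 1e12).k_hat
        assert np.max(np.abs(k - k0)) <= 1e-6 * np.linalg.norm(k0)


class TestMixedEstimate:
    def test_reduces_to_ridge_and_adaptive(self, rng):
        S = rng.standard_normal((30, 5))
        r = rng.standard_normal(30)
        k0 = rng.standard_normal(5)
        np.testing.assert_allclose(
            mixed_estimate(S, r, k0, 2.5, 0.0).k_hat,
            ridge_estimate(S, r, 2.5).k_hat, atol=1e-12)
        np.testing.assert_allclose(
            mixed_estimate(S, r, k0, 0.0, 3.5).k_hat,
            adaptive_estimate(S, r, k0, 3.5).k_hat, atol=1e-12)

    def test_hand_example(self):
        k = mixed_estimate(np.eye(2), np.ones(2), np.ones(2), 1.0, 1.0).k_hat
        np.testing.assert_allclose(k, [2.0 / 3.0, 2.0 / 3.0])

    def test_superposition_in_response_and_prior(self, rng):
        """The estimator is linear in (r, k_prior) jointly."""
        S = rng.standard_normal((25, 6))
        r1, r2 = rng.standard_normal((2, 25))
        k1, k2 = rng.standard_normal((2, 6))
        a, b = 1.3, 0.7
        lhs = mixed_estimate(S, a * r1 + b * r2, a * k1 + b * k2,
                             2.0, 5.0).k_hat
        rhs = (a * mixed_estimate(S, r1, k1, 2.0, 5.0).k_hat
               + b * mixed_estimate(S, r2, k2, 2.0, 5.0).k_hat)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


@pytest.mark.parametrize("lam_a, lam_b", [(0.0, 0.0), (3.0, 0.0),
                                          (0.0, 4.0), (2.0, 7.0)])
def test_all_estimators_match_quadratic_program_oracle(rng, lam_a, lam_b):
    S = rng.standard_normal((20, 5))
    r = rng.standard_normal(20)
    k0 = rng.standard_normal(5)
    expected = qp_oracle(S, r, lam_a, lam_b, k0)
    if lam_a == lam_b == 0.0:
        got = ml_estimate(S, r).k_hat
    elif lam_b == 0.0:
        got = ridge_estimate(S, r, lam_a).k_hat
    elif lam_a == 0.0:
        got = adaptive_estimate(S, r, k0, lam_b).k_hat
    else:
        got = mixed_estimate(S, r, k0, lam_a, lam_b).k_hat
    np.testing.assert_allclose(got, expected, atol=1e-8)


def _onset_filter(D, latency, scale_pos=1.0, scale_neg=1.0):
    """Temporal onset RF: positive lobe then symmetric negative lobe."""
    t = np.arange(D, dtype=float)
    pos = np.exp(-0.5 * ((t - latency) / 1.5) ** 2)
    neg = np.exp(-0.5 * ((t - latency - 4.0) / 1.5) ** 2)
    return scale_pos * pos - scale_neg * neg


def _cv_grid_select(S, r, estimator, grid):
    """2-fold CV on squared prediction error (independent of estimators)."""
    n = S.shape[0] // 2
    best, best_err = None, np.inf
    for g in grid:
        err = 0.0
        for tr, te in (((slice(0, n)), slice(n, None)),
                       ((slice(n, None)), slice(0, n))):
            k = estimator(S[tr], r[tr], g)
            err += float(np.sum((r[te] - S[te] @ k) ** 2))
        if err < best_err:
            best, best_err = g, err
    return best


def test_mismatched_prior_simulation_mixed_wins_on_average():
    """Short correlated-noise recordings with a rescaled, latency-shifted
    prior: the mixed estimator recovers the true filter at least as well
    as the purely adaptive and purely zero-mean ones on average."""
    from scipy.ndimage import gaussian_filter1d
    D, N = 20, 1000
    k_true = _onset_filter(D, 6.0)
    # hypothetical long-run static estimate: rescaled and shifted onset
    k_prior = _onset_filter(D, 7.5, scale_pos=1.6, scale_neg=0.7)
    alphas = np.logspace(-1, 3, 5)
    betas = np.logspace(-1, 3, 5)
    # the mixed grid includes both boundary limits (pure ridge, pure
    # adaptive) exactly as the mixed prior formulation allows
    mixed_grid = [(a, b) for a in [0.0, *alphas] for b in [0.0, *betas]
                  if a + b > 0]
    cc = {"zero": [], "adaptive": [], "mixed": []}
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        # noise correlation length comparable to the filter extent
        x = gaussian_filter1d(rng.standard_normal(N + D), 5.0, mode="wrap")
        x /= x.std()
        S = np.lib.stride_tricks.sliding_window_view(x, D)[:N]
        z = S @ k_true
        p = np.clip(0.12 * np.exp((z - z.mean()) / (2 * z.std())), 0, 1)
        r = (rng.random(N) < p).astype(float)
        a = _cv_grid_select(S, r, lambda S_, r_, g:
                            ridge_estimate(S_, r_, g).k_hat, alphas)
        cc["zero"].append(rf_correlation(
            ridge_estimate(S, r, a).k_hat, k_true))
        b = _cv_grid_select(S, r, lambda S_, r_, g:
                            adaptive_estimate(S_, r_, k_prior, g).k_hat,
                            betas)
        cc["adaptive"].append(rf_correlation(
            adaptive_estimate(S, r, k_prior, b).k_hat, k_true))
        ab = _cv_grid_select(S, r, lambda S_, r_, g:
                             mixed_estimate(S_, r_, k_prior, *g).k_hat,
                             mixed_grid)
        cc["mixed"].append(rf_correlation(
            mixed_estimate(S, r, k_prior, *ab).k_hat, k_true))
    assert np.mean(cc["mixed"]) >= np.mean(cc["adaptive"])
    assert np.mean(cc["mixed"]) >= np.mean(cc["zero"])
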