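"""Closed-form receptive-field estimators for the linear-Gaussian model.

For a design matrix ``S`` (rows = lagged stimulus patches) and a real
response ``r``, the maximum-likelihood estimate is the ordinary
least-squares solution; Gaussian priors on the filter coefficients yield
MAP estimates that add an isotropic penalty to the normal matrix:

* zero-mean prior (ridge):      k = (S'S + a I)^-1 S'r
* adaptive prior (mean k0):     k = (S'S + b I)^-1 (S'r + b k0)
* mixed prior (both):           k = (S'S + (a + b) I)^-1 (S'r + b k0)

All solves use a Cholesky factorization of the regularized normal matrix
rather than explicit inversion: with strongly correlated stimuli the
normal matrix is badly conditioned and the factorization form is the
numerically robust choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datamodel import PriorSpec, ReceptiveField

__all__ = [
    "LinearFitResult",
    "ml_estimate",
    "ridge_estimate",
    "adaptive_estimate",
    "mixed_estimate",
]


@dataclass
class LinearFitResult:
    """Result of a closed-form linear fit."""

    k_hat: np.ndarray
    prior: PriorSpec
    min_eigval: float  # smallest eigenvalue of the regularized normal matrix


def _solve_normal(S: np.ndarray, rhs: np.ndarray, penalty: float):
    """Solve (S'S + penalty*I) k = rhs via Cholesky; returns (k, min_eig)."""
    S = np.asarray(S, dtype=float)
    D = S.shape[1]
    A = S.T @ S + penalty * np.eye(D)
    min_eig = float(linalg.eigvalsh(A, subset_by_index=[0, 0])[0])
    if min_eig <= 1e-12 * max(1.0, float(np.trace(A)) / D):
        raise np.linalg.LinAlgError(
            "normal matrix is (numerically) rank-deficient; "
            "add regularization (alpha/beta > 0)"
        )
    c, low = linalg.cho_factor(A, lower=True)
    return linalg.cho_solve((c, low), rhs), min_eig


def ml_estimate(S: np.ndarray, r: np.ndarray) -> LinearFitResult:
    """Maximum-likelihood (ordinary least squares) filter estimate."""
    k, eig = _solve_normal(S, np.asarray(S).T @ np.asarray(r, dtype=float), 0.0)
    return LinearFitResult(k_hat=k, prior=PriorSpec("zero_mean", alpha=0.0),
                           min_eigval=eig)


def ridge_estimate(S: np.ndarray, r: np.ndarray, alpha: float) -> LinearFitResult:
    """MAP estimate under the zero-mean Gaussian prior (ridge regression).

    ``alpha = 0`` recovers the ML estimate; ``alpha -> inf`` shrinks the
    estimate toward (a scaled) spike-triggered average ``S'r / alpha``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    k, eig = _solve_normal(S, np.asarray(S).T @ np.asarray(r, dtype=float),
                           alpha)
    return LinearFitResult(k_hat=k, prior=PriorSpec("zero_mean", alpha=alpha),
                           min_eigval=eig)


def adaptive_estimate(S_t: np.ndarray, r_t: np.ndarray,
                      k_prior: np.ndarray, beta: float) -> LinearFitResult:
    """MAP estimate under the Gaussian prior centered at ``k_prior``.

    The right-hand side mixes the stimulus-response cross-correlation with
    the prior mean; ``beta`` controls how strongly the local estimate is
    pulled toward ``k_prior``.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    S_t = np.asarray(S_t, dtype=float)
    k_prior = np.asarray(k_prior, dtype=float).ravel()
    if k_prior.size != S_t.shape[1]:
        raise ValueError("prior mean dimension mismatch")
    rhs = S_t.T @ np.asarray(r_t, dtype=float) + beta * k_prior
    k, eig = _solve_normal(S_t, rhs, beta)
    prior = PriorSpec("adaptive", beta=beta,
                      prior_mean=_wrap_prior(k_prior))
    return LinearFitResult(k_hat=k, prior=prior, min_eigval=eig)


def mixed_estimate(S_t: np.ndarray, r_t: np.ndarray, k_prior: np.ndarray,
                   lambda_alpha: float, lambda_beta: float) -> LinearFitResult:
    """MAP estimate under the product of zero-mean and adaptive priors.

    ``lambda_beta = 0`` reduces to ridge with ``alpha = lambda_alpha``;
    ``lambda_alpha = 0`` reduces to the adaptive estimator.
    """
    if lambda_alpha < 0 or lambda_beta < 0:
        raise ValueError("prior strengths must be non-negative")
    S_t = np.asarray(S_t, dtype=float)
    k_prior = np.asarray(k_prior, dtype=float).ravel()
    if k_prior.size != S_t.shape[1]:
        raise ValueError("prior mean dimension mismatch")
    rhs = S_t.T @ np.asarray(r_t, dtype=float) + lambda_beta * k_prior
    k, eig = _solve_normal(S_t, rhs, lambda_alpha + lambda_beta)
    prior = PriorSpec("mixed", alpha=lambda_alpha, beta=lambda_beta,
                      prior_mean=_wrap_prior(k_prior))
    return LinearFitResult(k_hat=k, prior=prior, min_eigval=eig)


def _wrap_prior(k: np.ndarray) -> ReceptiveField:
    # store a flat prior-mean vector as a 1 x D receptive field
    return ReceptiveField(k=k, b=0.0, n_channels=1, n_lags=k.size, dt_s=1.0)
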