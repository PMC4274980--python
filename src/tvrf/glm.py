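"""Bernoulli GLM with logistic link and Gaussian filter priors.

Each time bin carries a binary spike indicator ``r_i`` modeled as
Bernoulli with probability ``f(z_i)``, ``z_i = s_i' k + b`` and ``f`` the
logistic function.  MAP estimation maximizes the penalized log-likelihood

    sum_i [ r_i z_i - log(1 + exp(z_i)) ]
        - (alpha/2) k'k - (beta/2) (k - k0)'(k - k0)

where ``k0`` is the prior mean (the static receptive field when fitting
local filters) and the offset ``b`` is never penalized, so the mean rate
can always be matched even under a strong prior.  The objective is
concave; it is maximized with a trust-region Newton conjugate-gradient
method using the analytic gradient and Hessian-vector product.
Hyperparameters are selected by stratified k-fold cross-validation on the
held-out Bernoulli log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .datamodel import LaggedDesign, PriorSpec, ReceptiveField

__all__ = [
    "GlmFit",
    "CvResult",
    "logistic",
    "bernoulli_ll",
    "penalized_objective",
    "fit_map",
    "default_grid",
    "cv_select_hyperparams",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 200
_SEPARABLE_NORM = 1e2


def logistic(z):
    """Numerically stable logistic function 1 / (1 + exp(-z)).

    For very negative ``z`` the value is computed as
    ``exp(z) / (1 + exp(z))`` so it underflows gracefully to the nearest
    subnormal rather than to zero via ``1 / inf``.
    """
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def bernoulli_ll(r: np.ndarray, z: np.ndarray) -> float:
    """Bernoulli log-likelihood sum_i [r_i z_i - log(1 + exp(z_i))].

    ``r`` must be binary; ``z`` is the linear predictor.  The softplus
    term is evaluated as ``logaddexp(0, z)`` so large |z| neither
    overflows nor loses precision.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    if r.shape != z.shape:
        raise ValueError("r and z must have equal length")
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError("response must be binary")
    return float(np.sum(r * z - np.logaddexp(0.0, z)))


def penalized_objective(k_t: np.ndarray, b_t: float, S_t: np.ndarray,
                        r_t: np.ndarray, prior: PriorSpec):
    """Penalized log-likelihood and its exact gradient.

    Returns ``(value, (grad_k, grad_b))`` for the objective maximized by
    :func:`fit_map`.  The offset gradient is unpenalized.
    """
    S_t = np.asarray(S_t, dtype=float)
    k_t = np.asarray(k_t, dtype=float).ravel()
    r_t = np.asarray(r_t, dtype=float)
    if k_t.size != S_t.shape[1]:
        raise ValueError("filter dimension mismatch")
    k0 = prior.mean_vector(k_t.size)
    z = S_t @ k_t + b_t
    value = bernoulli_ll(r_t, z)
    value -= 0.5 * prior.alpha * float(k_t @ k_t)
    dk = k_t - k0
    value -= 0.5 * prior.beta * float(dk @ dk)
    resid = r_t - expit(z)
    grad_k = S_t.T @ resid - prior.alpha * k_t - prior.beta * dk
    grad_b = float(resid.sum())
    return value, (grad_k, grad_b)


@dataclass
class GlmFit:
    """MAP fit of the Bernoulli GLM for one data (sub)set."""

    rf: ReceptiveField
    objective_value: float
    grad_norm: float
    n_iter: int
    converged: bool
    prior: PriorSpec


@dataclass
class CvResult:
    """Cross-validation summary over a hyperparameter grid."""

    grid: list[tuple[float, float]]
    mean_heldout_ll: np.ndarray
    selected: tuple[float, float]
    fold_assignments: np.ndarray
    seed: int
    extras: dict = field(default_factory=dict)


def _design_arrays(S):
    if isinstance(S, LaggedDesign):
        return S.S, S.n_channels, S.L, S.dt_s
    S = np.asarray(S, dtype=float)
    return S, 1, S.shape[1], 1.0


def fit_map(S_t, r_t, prior: PriorSpec, init: np.ndarray | None = None,
            tol: float = DEFAULT_TOL,
            max_iter: int = DEFAULT_MAX_ITER) -> GlmFit:
    """Maximize the penalized Bernoulli log-likelihood.

    Parameters
    ----------
    S_t : LaggedDesign or ndarray (N, D)
        Stimulus design rows for the (sub)set being fit.
    r_t : ndarray (N,)
        Binary spike indicators aligned to the rows.
    prior : PriorSpec
        Prior kind and strengths; the prior mean is required when
        ``beta > 0``.
    init : ndarray (D + 1,), optional
        Initial ``(k, b)``.  The solution of a strictly concave problem
        (``alpha + beta > 0``) does not depend on it.

    Returns
    -------
    GlmFit
        Converged flag is set when the gradient infinity-norm at the
        solution is at most ``tol``; on non-convergence the best iterate
        is still returned.
    """
    S, F, L, dt = _design_arrays(S_t)
    r = np.asarray(r_t, dtype=float).ravel()
    if r.size != S.shape[0]:
        raise ValueError("response length does not match design rows")
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError("response must be binary")
    D = S.shape[1]
    k0 = prior.mean_vector(D)
    reg = prior.alpha + prior.beta
    unpenalized = reg == 0.0

    def neg_obj(theta):
        k, b = theta[:-1], theta[-1]
        z = S @ k + b
        val = float(np.sum(r * z - np.logaddexp(0.0, z)))
        val -= 0.5 * prior.alpha * float(k @ k)
        d = k - k0
        val -= 0.5 * prior.beta * float(d @ d)
        resid = r - expit(z)
        g = np.empty_like(theta)
        g[:-1] = S.T @ resid - prior.alpha * k - prior.beta * d
        g[-1] = resid.sum()
        return -val, -g

    def neg_hessp(theta, v):
        z = S @ theta[:-1] + theta[-1]
        p = expit(z)
        w = p * (1.0 - p)
        u = S @ v[:-1] + v[-1]
        wu = w * u
        hv = np.empty_like(v)
        hv[:-1] = S.T @ wu + reg * v[:-1]
        hv[-1] = wu.sum()
        return hv

    if init is None:
        init = np.zeros(D + 1)
    init = np.asarray(init, dtype=float).ravel()
    if init.size != D + 1:
        raise ValueError("init must have length D + 1")

    def guard(theta):
        if unpenalized and np.linalg.norm(theta[:-1]) > _SEPARABLE_NORM:
            raise RuntimeError(
                "filter norm diverged during unpenalized fitting; the data "
                "are likely linearly separable -- use alpha or beta > 0"
            )

    res = optimize.minimize(
        neg_obj, init, jac=True, hessp=neg_hessp, method="trust-ncg",
        callback=guard, options={"gtol": tol, "maxiter": max_iter},
    )
    theta = res.x
    val, g = neg_obj(theta)
    gnorm = float(np.max(np.abs(g)))
    rf = ReceptiveField(k=theta[:-1], b=float(theta[-1]), n_channels=F,
                        n_lags=L, dt_s=dt,
                        fit_meta={"prior": prior.kind, "alpha": prior.alpha,
                                  "beta": prior.beta})
    return GlmFit(rf=rf, objective_value=-val, grad_norm=gnorm,
                  n_iter=int(res.nit), converged=bool(gnorm <= tol),
                  prior=prior)


def default_grid(with_beta: bool, n: int = 7) -> list[tuple[float, float]]:
    """Default crossed hyperparameter grid: log-spaced 1e-2 ... 1e4."""
    vals = np.logspace(-2, 4, n)
    if with_beta:
        return [(float(a), float(b)) for a in vals for b in vals]
    return [(float(a), 0.0) for a in vals]


def cv_select_hyperparams(S, r, prior_mean: ReceptiveField | None,
                          grid: list[tuple[float, float]] | None = None,
                          n_folds: int = 5, seed: int = 0,
                          tol: float = DEFAULT_TOL,
                          max_iter: int = DEFAULT_MAX_ITER) -> CvResult:
    """Select (alpha, beta) by stratified k-fold cross-validation.

    Folds are random and stratified by spike presence so every fold holds
    approximately the global spike fraction.  The pair maximizing the mean
    held-out Bernoulli log-likelihood wins; ties break toward larger
    ``alpha + beta`` (the more conservative, more strongly regularized
    model).
    """
    S_arr, _, _, _ = _design_arrays(S)
    r = np.asarray(r, dtype=float).ravel()
    n_spikes = int(r.sum())
    if n_spikes == 0 or n_spikes == r.size:
        raise ValueError("degenerate Bernoulli response (all zeros or all ones)")
    if n_spikes < n_folds:
        raise ValueError(f"need at least {n_folds} spikes for {n_folds}-fold "
                         "stratified CV")
    if grid is None:
        grid = default_grid(with_beta=prior_mean is not None)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    for a, b in grid:
        if b > 0 and prior_mean is None:
            raise ValueError("grid contains beta > 0 but no prior mean given")

    kind = "zero_mean" if prior_mean is None else "mixed"
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(S_arr, r.astype(int)))
    fold_assignments = np.empty(r.size, dtype=int)
    for j, (_, test_idx) in enumerate(folds):
        fold_assignments[test_idx] = j

    # sweep the grid from strong to weak regularization per fold, warm
    # starting each fit from the previous solution
    order = sorted(range(len(grid)), key=lambda i: -(grid[i][0] + grid[i][1]))
    ll = np.zeros((len(grid), n_folds))
    for j, (train_idx, test_idx) in enumerate(folds):
        S_tr, r_tr = S_arr[train_idx], r[train_idx]
        S_te, r_te = S_arr[test_idx], r[test_idx]
        init = None
        for i in order:
            a, b = grid[i]
            prior = PriorSpec(kind, alpha=a, beta=b, prior_mean=prior_mean)
            fit = fit_map(S_tr, r_tr, prior, init=init, tol=tol,
                          max_iter=max_iter)
            init = np.append(fit.rf.k, fit.rf.b)
            ll[i, j] = bernoulli_ll(r_te, S_te @ fit.rf.k + fit.rf.b)
    mean_ll = ll.mean(axis=1)
    # argmax with ties toward larger alpha + beta
    best = max(range(len(grid)),
               key=lambda i: (mean_ll[i], grid[i][0] + grid[i][1]))
    return CvResult(grid=list(grid), mean_heldout_ll=mean_ll,
                    selected=grid[best], fold_assignments=fold_assignments,
                    seed=seed, extras={"per_fold_ll": ll})
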