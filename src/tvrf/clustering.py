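"""GMM clustering of pooled bootstrap local RFs with BIC model selection.

Pooled local RF estimates (all bootstrap replicates of all parts) are fit
with a diagonal-covariance Gaussian mixture; the number of components K
is chosen by minimizing the Bayesian information criterion

    BIC = -2 log L + d log N,    d = K (2 D + 1) - 1,

where D is the RF dimensionality and N the number of pooled estimates.
EM is restarted from several random-responsibility initializations and
the best restart (by log-likelihood) kept.  The mixture deliberately uses
no temporal information: any temporally localized cluster structure in
the occupancy timecourse is induced purely by the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .datamodel import Partition

__all__ = ["GMMModel", "ClusterTimecourse", "fit_gmm", "select_k_bic",
           "cluster_timecourse", "gmm_bic"]

EM_TOL = 1e-7
EM_MAX_ITER = 500


@dataclass
class GMMModel:
    """Fitted diagonal-covariance Gaussian mixture over RF vectors."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    d: int
    seed: int
    _sk: GaussianMixture | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard cluster assignment (argmax responsibility) per row."""
        if self._sk is None:
            raise RuntimeError("model carries no fitted estimator")
        return self._sk.predict(np.asarray(X, dtype=float))

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        if self._sk is None:
            raise RuntimeError("model carries no fitted estimator")
        return self._sk.predict_proba(np.asarray(X, dtype=float))


@dataclass
class ClusterTimecourse:
    """Occupancy of clusters over parts under the majority rule.

    ``occupancy[j, c]`` counts bootstrap estimates of part ``j`` assigned
    to cluster ``c`` (rows sum to n_boot).  A part *qualifies* for a
    cluster when more than half of its bootstrap estimates are assigned
    to it; ``occurrences[c]`` counts maximal contiguous runs of
    qualifying parts and ``extent_s[c]`` their total duration (qualifying
    parts x T_shift).
    """

    occupancy: np.ndarray
    occurrences: np.ndarray
    extent_s: np.ndarray
    n_boot: int
    t_shift_s: float


def gmm_bic(log_likelihood: float, K: int, D: int, N: int) -> float:
    """BIC = -2 log L + d log N with d = K(2D+1) - 1 free parameters."""
    d = K * (2 * D + 1) - 1
    return -2.0 * log_likelihood + d * np.log(N)


def _fit_once(X: np.ndarray, K: int, seed: int, restarts: int,
              variance_floor: float, covariance: str) -> GaussianMixture:
    gm = GaussianMixture(
        n_components=K, covariance_type=covariance, tol=EM_TOL,
        max_iter=EM_MAX_ITER, n_init=restarts, init_params="random",
        reg_covar=variance_floor, random_state=seed,
    )
    gm.fit(X)
    return gm


def fit_gmm(X: np.ndarray, K: int, seed: int = 0, restarts: int = 1,
            variance_floor: float | None = None,
            covariance: str = "diag") -> GMMModel:
    """Fit a K-component diagonal-covariance mixture by EM.

    EM runs to convergence (log-likelihood change <= 1e-7 per sample or
    500 iterations); with ``restarts > 1`` the best run by log-likelihood
    is kept.  The variance floor defaults to 1e-6 of the mean global
    variance to prevent component collapse.  If a component empties out
    (vanishing weight), the fit is re-seeded once before raising.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (estimates x dimensions)")
    N, D = X.shape
    if N < K:
        raise ValueError(f"need at least K={K} rows, got {N}")
    if variance_floor is None:
        variance_floor = 1e-6 * float(np.var(X, axis=0).mean())
        variance_floor = max(variance_floor, 1e-12)
    gm = _fit_once(X, K, seed, restarts, variance_floor, covariance)
    if gm.weights_.min() * N < 0.5:  # effectively empty component
        gm = _fit_once(X, K, seed + 1, restarts, variance_floor, covariance)
        if gm.weights_.min() * N < 0.5:
            raise RuntimeError(
                f"component emptied during EM for K={K} even after "
                "re-seeding; reduce K"
            )
    logL = float(gm.score(X) * N)
    variances = (gm.covariances_ if covariance == "diag"
                 else np.array([np.diag(c) for c in
                                np.atleast_3d(gm.covariances_)]))
    return GMMModel(K=K, weights=gm.weights_.copy(), means=gm.means_.copy(),
                    variances=np.asarray(variances, dtype=float),
                    log_likelihood=logL,
                    bic=gmm_bic(logL, K, D, N),
                    d=K * (2 * D + 1) - 1, seed=seed, _sk=gm)


def select_k_bic(X: np.ndarray, k_range=range(1, 21), restarts: int = 10,
                 seed: int = 0,
                 variance_floor: float | None = None
                 ) -> tuple[GMMModel, dict[int, float]]:
    """Fit mixtures over ``k_range`` and return the BIC-minimizing model.

    Returns the winning model and the full ``{K: BIC}`` table.
    ``restarts`` EM runs from different random initial conditions are
    performed for each K.
    """
    X = np.asarray(X, dtype=float)
    ks = [int(k) for k in k_range]
    if X.shape[0] < max(ks):
        raise ValueError("fewer rows than the largest K requested")
    table: dict[int, float] = {}
    best: GMMModel | None = None
    for k in ks:
        model = fit_gmm(X, k, seed=seed, restarts=restarts,
                        variance_floor=variance_floor)
        table[k] = model.bic
        if best is None or model.bic < best.bic:
            best = model
    assert best is not None
    return best, table


def cluster_timecourse(model: GMMModel, assignments: np.ndarray,
                       partition: Partition | None = None,
                       t_shift_s: float | None = None) -> ClusterTimecourse:
    """Occupancy matrix and occurrence/extent statistics per cluster.

    ``assignments`` has shape (parts, n_boot): the hard cluster label of
    every bootstrap local RF.  A part belongs to a cluster's timecourse
    only when *more than half* of its bootstrap estimates fall in that
    cluster; an occurrence is a maximal contiguous run of such parts.
    """
    assignments = np.asarray(assignments, dtype=int)
    if assignments.ndim != 2:
        raise ValueError("assignments must be (parts x n_boot)")
    P, n_boot = assignments.shape
    if t_shift_s is None:
        if partition is None:
            raise ValueError("need a partition or an explicit t_shift_s")
        t_shift_s = partition.t_shift_s
    K = model.K
    occupancy = np.zeros((P, K), dtype=int)
    for j in range(P):
        occupancy[j] = np.bincount(assignments[j], minlength=K)
    majority = occupancy > n_boot / 2.0  # strictly more than half
    occurrences = np.zeros(K, dtype=int)
    extent = np.zeros(K)
    for c in range(K):
        col = majority[:, c]
        # count maximal contiguous runs of True
        occurrences[c] = int(np.sum(col[1:] & ~col[:-1])) + int(col[0])
        extent[c] = col.sum() * t_shift_s
    return ClusterTimecourse(occupancy=occupancy, occurrences=occurrences,
                             extent_s=extent, n_boot=n_boot,
                             t_shift_s=float(t_shift_s))
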