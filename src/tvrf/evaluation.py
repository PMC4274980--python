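"""Similarity and prediction metrics for static and local RF estimates.

* ``rf_correlation`` -- normalized subspace projection (cosine
  similarity) between two RF vectors; offsets are excluded.
* ``cc_trace`` -- per-part mean/std of the correlation between bootstrap
  local RFs and the static RF, with per-part spike counts.
* ``timevarying_bll`` -- time-dependent Bernoulli log-likelihood: the
  log-likelihood summed over parts, each evaluated with that part's
  local parameters.
* ``prediction_protocol`` -- repeated random subsampling: 10% of the
  data held out (stratified by spike presence), static RF fit on the
  remaining 90%, local RFs fit on non-overlapping parts with the
  validation rows removed, and the held-out Bernoulli log-likelihood of
  static / local / full models compared after normalizing by the full
  model (fit on everything, validation included).  Values above zero
  mean the cross-validated model out-predicts the best static fit that
  even saw the validation data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import train_test_split

from .datamodel import (LaggedDesign, PriorSpec, SpikeTrain,
                        StimulusEnsemble, build_design_matrix)
from .glm import bernoulli_ll, cv_select_hyperparams, default_grid, fit_map
from .timevarying import LocalRFSequence, fit_local_sequence, fit_static, \
    make_partition

logger = logging.getLogger(__name__)

__all__ = ["CcTrace", "BllReport", "rf_correlation", "cc_trace",
           "timevarying_bll", "prediction_protocol", "cc_spike_correlation"]


@dataclass
class CcTrace:
    """Per-part similarity of local RFs to the static RF."""

    starts_s: np.ndarray
    cc_mean: np.ndarray
    cc_sd: np.ndarray
    n_spikes: np.ndarray


@dataclass
class BllReport:
    """Held-out Bernoulli log-likelihoods per replicate.

    Normalized values subtract the full model's BLL, so
    ``normalized(full) = 0`` identically.
    """

    bll_static: np.ndarray
    bll_local: np.ndarray
    bll_full: np.ndarray
    offsets_s: np.ndarray
    seeds: np.ndarray
    n_val_rows: np.ndarray
    extras: dict = field(default_factory=dict)

    @property
    def normalized_static(self) -> np.ndarray:
        return self.bll_static - self.bll_full

    @property
    def normalized_local(self) -> np.ndarray:
        return self.bll_local - self.bll_full

    @property
    def normalized_full(self) -> np.ndarray:
        return np.zeros_like(self.bll_full)


def rf_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized inner product u'v / (|u| |v|) between two RF vectors.

    1 means identical direction, 0 orthogonal, -1 opposite.  Offset terms
    are not part of the RF vectors and must not be included.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size or u.size == 0:
        raise ValueError("vectors must have equal nonzero length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("correlation undefined for a zero vector")
    return float(u @ v / (nu * nv))


def cc_trace(seq: LocalRFSequence, r_rows: np.ndarray) -> CcTrace:
    """Mean/std of cc(local bootstrap RF, static RF) per part.

    ``r_rows`` is the binary response aligned to design rows (used for
    the per-part spike counts).  Skipped parts yield NaN.
    """
    k_static = seq.static_rf.k
    P = seq.n_parts
    mean = np.full(P, np.nan)
    sd = np.full(P, np.nan)
    counts = np.zeros(P, dtype=int)
    for j, fits in enumerate(seq.locals):
        counts[j] = int(np.asarray(r_rows)[seq.partition.parts[j]].sum())
        if fits:
            ccs = [rf_correlation(f.rf.k, k_static) for f in fits]
            mean[j] = np.mean(ccs)
            sd[j] = np.std(ccs)
    return CcTrace(starts_s=np.asarray(seq.partition.starts_s),
                   cc_mean=mean, cc_sd=sd, n_spikes=counts)


def timevarying_bll(r_rows: np.ndarray, S: np.ndarray,
                    part_params: list[tuple[np.ndarray, float]],
                    heldout_rows: list[np.ndarray]) -> float:
    """Time-dependent Bernoulli log-likelihood over held-out rows.

    ``part_params[j] = (k_t, b_t)`` are the local parameters of part
    ``j`` and ``heldout_rows[j]`` the held-out row indices assigned to
    it.  Every held-out row must be assigned to exactly one part.
    """
    if len(part_params) != len(heldout_rows):
        raise ValueError("one parameter pair per part required")
    r_rows = np.asarray(r_rows, dtype=float)
    total = 0.0
    seen = np.zeros(r_rows.size, dtype=bool)
    for (k, b), rows in zip(part_params, heldout_rows):
        rows = np.asarray(rows, dtype=int)
        if rows.size == 0:
            continue
        if seen[rows].any():
            raise ValueError("held-out row assigned to more than one part")
        seen[rows] = True
        z = S[rows] @ np.asarray(k, dtype=float).ravel() + b
        total += bernoulli_ll(r_rows[rows], z)
    return total


def prediction_protocol(ens: StimulusEnsemble, spikes: SpikeTrain,
                        t_win_s: float, t_part_s: float = 20.0,
                        offsets_s=(0.0, 5.0, 10.0, 15.0),
                        val_frac: float = 0.1, n_reps: int = 10,
                        seed: int = 0,
                        grid_static=None, grid_local=None, n_folds: int = 5,
                        min_spikes: int = 5,
                        reuse_hyperparams: bool = True) -> BllReport:
    """Repeated random-subsampling comparison of static vs local RFs.

    Each replicate pairs a fresh stratified 90/10 train/validation split
    with one part offset ``t0`` (cycling through ``offsets_s``):

    1. static RF: zero-mean-prior GLM, CV-selected alpha, training rows;
    2. full model: same fit on *all* rows (the normalization reference);
    3. local RFs: mixed-prior GLM per non-overlapping ``t_part_s`` part
       (offset ``t0``), validation rows removed, static RF as prior mean;
    4. the three Bernoulli log-likelihoods on the validation rows.

    Validation rows falling outside every part (or in a part skipped for
    too few spikes) are excluded from all three likelihoods, keeping the
    comparison paired.
    """
    design = build_design_matrix(ens, t_win_s)
    r = design.response(spikes)
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(n_reps)]
    out = {name: [] for name in ("static", "local", "full", "nval")}
    offs = []
    for rep in range(n_reps):
        rs = rep_seeds[rep]
        t0 = float(offsets_s[rep % len(offsets_s)])
        offs.append(t0)
        idx = np.arange(design.n_rows)
        train_rows, val_rows = train_test_split(
            idx, test_size=val_frac, random_state=rs,
            stratify=r.astype(int))
        train_rows.sort(); val_rows.sort()

        static_rf = fit_static(ens, spikes, t_win_s, grid=grid_static,
                               n_folds=n_folds, seed=rs, design=design,
                               rows=train_rows)
        full_rf = fit_static(ens, spikes, t_win_s, grid=grid_static,
                             n_folds=n_folds, seed=rs, design=design)

        partition = make_partition(ens, t_part_s, t_part_s, t0_s=t0,
                                   design=design)
        seq = fit_local_sequence(
            ens, spikes, static_rf, partition, prior_kind="mixed",
            bootstrap_frac=1.0, n_boot=1, seed=rs, grid=grid_local,
            n_folds=n_folds, min_spikes=min_spikes, design=design,
            reuse_hyperparams=reuse_hyperparams, exclude_rows=val_rows)

        # assign validation rows to parts; drop rows in no usable part
        val_set = np.zeros(design.n_rows, dtype=bool)
        val_set[val_rows] = True
        part_params, heldout = [], []
        used = np.zeros(design.n_rows, dtype=bool)
        for j, rows in enumerate(partition.parts):
            if j in seq.skipped_parts:
                continue
            fits = seq.locals[j]
            k = np.mean([f.rf.k for f in fits], axis=0)
            b = float(np.mean([f.rf.b for f in fits]))
            hrows = rows[val_set[rows] & ~used[rows]]
            used[hrows] = True
            part_params.append((k, b))
            heldout.append(hrows)
        eval_rows = np.concatenate([h for h in heldout]) if heldout else \
            np.empty(0, dtype=int)
        if eval_rows.size == 0:
            raise ValueError("no validation rows fall inside any part")
        bll_local = timevarying_bll(r, design.S, part_params, heldout)
        z_static = design.S[eval_rows] @ static_rf.k + static_rf.b
        z_full = design.S[eval_rows] @ full_rf.k + full_rf.b
        out["static"].append(bernoulli_ll(r[eval_rows], z_static))
        out["full"].append(bernoulli_ll(r[eval_rows], z_full))
        out["local"].append(bll_local)
        out["nval"].append(eval_rows.size)
    return BllReport(bll_static=np.asarray(out["static"]),
                     bll_local=np.asarray(out["local"]),
                     bll_full=np.asarray(out["full"]),
                     offsets_s=np.asarray(offs),
                     seeds=np.asarray(rep_seeds),
                     n_val_rows=np.asarray(out["nval"]))


def cc_spike_correlation(trace: CcTrace, method: str = "pearson") -> float:
    """Correlation between the per-part cc trace and spike counts.

    Pearson by default; ``method='spearman'`` for the rank variant.
    Requires at least three parts and non-constant inputs.
    """
    ok = np.isfinite(trace.cc_mean)
    cc = trace.cc_mean[ok]
    n = trace.n_spikes[ok].astype(float)
    if cc.size < 3:
        raise ValueError("need at least three parts")
    if np.ptp(cc) == 0 or np.ptp(n) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        return float(stats.pearsonr(cc, n).statistic)
    if method == "spearman":
        return float(stats.spearmanr(cc, n).statistic)
    raise ValueError(f"unknown method '{method}'")
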