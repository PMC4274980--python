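"""Static and local (time-varying) receptive-field estimation workflow.

The core procedure: estimate a static RF from the whole stimulus-response
sequence with a zero-mean-prior GLM, divide the sequence into overlapping
parts (length ``T_part``, shift ``T_shift``), then estimate a local RF per
part with the static RF as the mean of an informative Gaussian prior
(mixed prior by default).  Each local RF is re-estimated on random 90%
subsets of the part's data to obtain bootstrap confidence information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (LaggedDesign, Partition, PriorSpec, ReceptiveField,
                        SpikeTrain, StimulusEnsemble, build_design_matrix)
from .glm import CvResult, GlmFit, cv_select_hyperparams, default_grid, fit_map

logger = logging.getLogger(__name__)

__all__ = ["LocalRFSequence", "make_partition", "fit_static",
           "fit_local_sequence"]

DEFAULT_T_PART_S = 20.0
DEFAULT_T_SHIFT_S = 5.0
MIN_SPIKES_PER_PART = 5


@dataclass
class LocalRFSequence:
    """Ordered local RF estimates (bootstrap replicates) per part."""

    static_rf: ReceptiveField
    partition: Partition
    locals: list[list[GlmFit]]
    bootstrap_frac: float
    n_boot: int
    seed: int
    skipped_parts: list[int] = field(default_factory=list)
    hyperparams: list = field(default_factory=list)

    @property
    def n_parts(self) -> int:
        return self.partition.n_parts

    def mean_local_filters(self) -> np.ndarray:
        """Bootstrap-averaged local filter per part, shape (P, D); NaN rows
        for skipped parts."""
        D = self.static_rf.k.size
        out = np.full((self.n_parts, D), np.nan)
        for j, fits in enumerate(self.locals):
            if fits:
                out[j] = np.mean([f.rf.k for f in fits], axis=0)
        return out


def make_partition(ens: StimulusEnsemble | LaggedDesign, t_part_s: float,
                   t_shift_s: float, t0_s: float = 0.0,
                   design: LaggedDesign | None = None) -> Partition:
    """Divide the recording into overlapping windows of design rows.

    Window ``j`` covers bins in ``[t0 + j*T_shift, t0 + j*T_shift +
    T_part)`` (seconds converted to bins by flooring), intersected with
    the rows of the design matrix, so silences and bins with incomplete
    history never contribute.  Full-length windows are generated while
    they fit; if they leave uncovered data at the end, one trailing
    shorter window is appended provided it is at least ``T_part / 2``
    long.  Empty windows (e.g. falling entirely into silence) are
    dropped with a warning.
    """
    if not (t_part_s >= t_shift_s > 0):
        raise ValueError("require t_part_s >= t_shift_s > 0")
    if t0_s < 0:
        raise ValueError("t0_s must be non-negative")
    if isinstance(ens, LaggedDesign):
        design = ens
        dt = design.dt_s
        duration_s = (int(design.row_bins.max()) + 1) * dt
    else:
        dt = ens.dt_s
        duration_s = ens.duration_s
        if design is None:
            raise ValueError("a LaggedDesign is required to define parts")
    starts_s: list[float] = []
    s = t0_s
    while s + t_part_s <= duration_s + 1e-9:
        starts_s.append(s)
        s += t_shift_s
    windows = [(x, x + t_part_s) for x in starts_s]
    if starts_s and starts_s[-1] + t_part_s < duration_s - 1e-9:
        # trailing shorter window covering the leftover, if long enough
        if duration_s - s >= t_part_s / 2.0:
            windows.append((s, duration_s))
            starts_s.append(s)
    if not windows:
        raise ValueError(
            f"no complete part of length {t_part_s} s fits into "
            f"{duration_s} s of data"
        )
    row_bins = design.row_bins
    parts, kept_starts = [], []
    for (a_s, b_s) in windows:
        a = int(np.floor(a_s / dt))
        b = int(np.floor(b_s / dt + 1e-9))
        rows = np.nonzero((row_bins >= a) & (row_bins < b))[0]
        if rows.size:
            parts.append(rows)
            kept_starts.append(a_s)
        else:
            logger.warning("part starting at %.3f s has no design rows; "
                           "dropped", a_s)
    if not parts:
        raise ValueError("every candidate part is empty of design rows")
    return Partition(t_part_s=t_part_s, t_shift_s=t_shift_s, t0_s=t0_s,
                     parts=parts, starts_s=kept_starts)


def fit_static(ens: StimulusEnsemble, spikes: SpikeTrain, t_win_s: float,
               grid: list[tuple[float, float]] | None = None,
               n_folds: int = 5, seed: int = 0,
               design: LaggedDesign | None = None,
               rows: np.ndarray | None = None) -> ReceptiveField:
    """Zero-mean-prior GLM fit on the whole sequence with CV-selected alpha.

    ``rows`` optionally restricts the fit to a subset of design rows
    (used by the prediction protocol to hold out validation data).
    """
    if design is None:
        design = build_design_matrix(ens, t_win_s)
    r = design.response(spikes)
    S = design.S
    if rows is not None:
        S, r = S[rows], r[rows]
    if r.sum() == 0:
        raise ValueError("no spikes in the training data")
    if grid is None:
        grid = default_grid(with_beta=False)
    cv = cv_select_hyperparams(S, r, None, grid=grid, n_folds=n_folds,
                               seed=seed)
    alpha, _ = cv.selected
    prior = PriorSpec("zero_mean", alpha=alpha)
    fit = fit_map(S, r, prior)
    rf = ReceptiveField(k=fit.rf.k, b=fit.rf.b, n_channels=design.n_channels,
                        n_lags=design.L, dt_s=design.dt_s,
                        fit_meta={"prior": "zero_mean", "alpha": alpha,
                                  "seed": seed, "cv_mean_ll":
                                  cv.mean_heldout_ll.tolist()})
    return rf


def fit_local_sequence(ens: StimulusEnsemble | None, spikes: SpikeTrain,
                       static_rf: ReceptiveField, partition: Partition,
                       prior_kind: str = "mixed",
                       bootstrap_frac: float = 0.9, n_boot: int = 10,
                       seed: int = 0,
                       grid: list[tuple[float, float]] | None = None,
                       n_folds: int = 5,
                       min_spikes: int = MIN_SPIKES_PER_PART,
                       design: LaggedDesign | None = None,
                       hyperparams: tuple[float, float] | None = None,
                       reuse_hyperparams: bool = False,
                       exclude_rows: np.ndarray | None = None,
                       ) -> LocalRFSequence:
    """Estimate one local RF per part, with bootstrap replicates.

    For every part and bootstrap replicate a random ``bootstrap_frac``
    subset of the part's design rows is drawn without replacement,
    hyperparameters are selected by CV on that subset (unless fixed via
    ``hyperparams`` or reused from the first part via
    ``reuse_hyperparams``), and the MAP filter is fit with the static RF
    as prior mean.  Parts with fewer than ``min_spikes`` spikes are
    flagged and skipped, not silently dropped.
    """
    if design is None:
        if ens is None:
            raise ValueError("need either a design matrix or an ensemble")
        design = build_design_matrix(ens, static_rf.t_win_s)
    if static_rf.k.size != design.n_dims:
        raise ValueError("static RF incompatible with design dimensions")
    r = design.response(spikes)
    if prior_kind not in ("mixed", "adaptive", "zero_mean"):
        raise ValueError(f"unknown prior kind '{prior_kind}'")
    prior_mean = None if prior_kind == "zero_mean" else static_rf
    if grid is None and hyperparams is None:
        if prior_kind == "mixed":
            grid = default_grid(with_beta=True)
        elif prior_kind == "adaptive":
            grid = [(0.0, b) for b in np.logspace(-2, 4, 7)]
        else:
            grid = default_grid(with_beta=False)

    excluded = (np.zeros(design.n_rows, dtype=bool) if exclude_rows is None
                else np.isin(np.arange(design.n_rows), exclude_rows))
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.spawn(partition.n_parts)
    locals_: list[list[GlmFit]] = []
    skipped: list[int] = []
    hp_used: list = []
    shared_hp = hyperparams
    for j, rows in enumerate(partition.parts):
        rows = rows[~excluded[rows]]
        fits: list[GlmFit] = []
        if int(r[rows].sum()) < min_spikes:
            logger.warning("part %d (start %.1f s): fewer than %d spikes; "
                           "skipped", j, partition.starts_s[j], min_spikes)
            skipped.append(j)
            locals_.append(fits)
            hp_used.append(None)
            continue
        boot_seeds = part_seeds[j].spawn(n_boot)
        part_hp = shared_hp
        for bseq in boot_seeds:
            rng = np.random.default_rng(bseq)
            n_sub = max(1, int(np.floor(bootstrap_frac * rows.size)))
            sub = rng.choice(rows, size=n_sub, replace=False)
            S_sub, r_sub = design.S[sub], r[sub]
            if part_hp is None:
                cv = cv_select_hyperparams(
                    S_sub, r_sub, prior_mean, grid=grid, n_folds=n_folds,
                    seed=int(rng.integers(2**31)))
                a, b = cv.selected
                if reuse_hyperparams:
                    part_hp = (a, b)
                    shared_hp = part_hp
            else:
                a, b = part_hp
            prior = PriorSpec(prior_kind, alpha=a, beta=b,
                              prior_mean=prior_mean)
            init = np.append(static_rf.k, static_rf.b)
            fits.append(fit_map(S_sub, r_sub, prior, init=init))
        hp_used.append(part_hp if part_hp is not None
                       else [(f.prior.alpha, f.prior.beta) for f in fits])
        locals_.append(fits)
    if skipped:
        logger.info("skipped %d of %d parts for having fewer than %d spikes",
                    len(skipped), partition.n_parts, min_spikes)
    return LocalRFSequence(static_rf=static_rf, partition=partition,
                           locals=locals_, bootstrap_frac=bootstrap_frac,
                           n_boot=n_boot, seed=seed, skipped_parts=skipped,
                           hyperparams=hp_used)
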