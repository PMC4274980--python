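"""Core domain types and stimulus/response preprocessing.

The estimation framework operates on a spectrogram-like stimulus (frequency
channels x time bins) paired with a binary spike train sampled on the same
time grid.  Stimulus history is exposed to the estimators through a lagged
design matrix whose rows are vectorized spectro-temporal patches.

Conventions
-----------
* Receptive-field vectors are frequency-major: ``k.reshape(F, L)`` recovers
  the frequency x lag filter, with lag index 0 the *oldest* bin of the
  window and lag index ``L - 1`` the bin of the response itself.
* Bin indices are 0-based in memory and on disk.  A spike at time ``t_s``
  belongs to bin ``i`` iff ``i * dt <= t_s < (i + 1) * dt`` (half-open).
* Contiguous stimulation is described by half-open ``[start, stop)`` bin
  intervals (``segments``); silence gaps between segments never contribute
  design rows, and no lag window crosses a segment boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StimulusEnsemble",
    "SpikeTrain",
    "LaggedDesign",
    "ReceptiveField",
    "PriorSpec",
    "Partition",
    "build_design_matrix",
    "bin_spikes",
]


@dataclass
class StimulusEnsemble:
    """Spectrogram stimulus with bin duration and stimulation segments.

    Parameters
    ----------
    spec : ndarray, shape (F, T)
        Real-valued spectrogram (typically log-compressed filter-bank
        magnitudes).
    dt_s : float
        Time-bin duration in seconds.
    freqs_hz : ndarray, shape (F,)
        Center frequency of each channel in Hz.
    segments : list of (int, int)
        Half-open, disjoint, sorted bin intervals of contiguous
        stimulation.  Defaults to one segment covering all bins.
    """

    spec: np.ndarray
    dt_s: float
    freqs_hz: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spec = np.asarray(self.spec, dtype=float)
        if self.spec.ndim != 2:
            raise ValueError("spec must be 2-D (F channels x T bins)")
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float).ravel()
        if self.freqs_hz.size != self.n_channels:
            raise ValueError(
                f"freqs_hz has {self.freqs_hz.size} entries for "
                f"{self.n_channels} channels"
            )
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")
        if not self.segments:
            self.segments = [(0, self.n_bins)]
        self.segments = [(int(a), int(b)) for a, b in self.segments]
        prev_stop = 0
        for a, b in self.segments:
            if not (0 <= a < b <= self.n_bins):
                raise ValueError(f"segment ({a}, {b}) outside [0, {self.n_bins})")
            if a < prev_stop:
                raise ValueError("segments must be sorted and disjoint")
            prev_stop = b

    @property
    def n_channels(self) -> int:
        return self.spec.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spec.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.dt_s


@dataclass
class SpikeTrain:
    """Binary spike response aligned to the stimulus time grid."""

    r: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r)
        if self.r.ndim != 1:
            raise ValueError("spike vector must be 1-D")
        if not np.isin(self.r, (0, 1)).all():
            raise ValueError("spike vector entries must be 0 or 1")
        self.r = self.r.astype(np.uint8)
        if not self.dt_s > 0:
            raise ValueError("dt_s must be positive")

    @property
    def n_bins(self) -> int:
        return self.r.size

    @property
    def n_spikes(self) -> int:
        return int(self.r.sum())


@dataclass
class LaggedDesign:
    """Lag-embedded stimulus: one row per bin with complete history.

    ``S`` has shape (N, D) with ``D = F * L``; ``row_bins[j]`` is the
    original bin index of row ``j``.  Row ``j`` contains the patch
    ``spec[:, row_bins[j] - L + 1 : row_bins[j] + 1]`` flattened
    frequency-major (lag oldest -> most recent).
    """

    S: np.ndarray
    row_bins: np.ndarray
    L: int
    n_channels: int
    dt_s: float

    @property
    def n_rows(self) -> int:
        return self.S.shape[0]

    @property
    def n_dims(self) -> int:
        return self.S.shape[1]

    def response(self, spikes: SpikeTrain) -> np.ndarray:
        """Spike values aligned to design rows (float vector)."""
        if spikes.n_bins <= int(self.row_bins.max(initial=-1)):
            raise ValueError("spike train shorter than stimulus")
        return spikes.r[self.row_bins].astype(float)


@dataclass
class ReceptiveField:
    """Linear filter ``k`` (frequency x lag, vectorized) plus offset ``b``."""

    k: np.ndarray
    b: float
    n_channels: int
    n_lags: int
    dt_s: float
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float).ravel()
        if self.k.size != self.n_channels * self.n_lags:
            raise ValueError(
                f"filter length {self.k.size} != F*L = "
                f"{self.n_channels * self.n_lags}"
            )
        if not np.all(np.isfinite(self.k)) or not np.isfinite(self.b):
            raise ValueError("receptive field has non-finite entries")

    @property
    def t_win_s(self) -> float:
        return self.n_lags * self.dt_s

    def as_matrix(self) -> np.ndarray:
        """Filter as (F, L) matrix, lag oldest -> most recent."""
        return self.k.reshape(self.n_channels, self.n_lags)


PRIOR_KINDS = ("zero_mean", "adaptive", "mixed")


@dataclass
class PriorSpec:
    """Gaussian prior on filter coefficients.

    ``alpha`` weights the zero-centered (ridge) component and ``beta`` the
    component centered on ``prior_mean``; the underlying prior variances
    enter only through these ratios.  ``zero_mean`` uses alpha only,
    ``adaptive`` beta only, ``mixed`` both.
    """

    kind: str
    alpha: float = 0.0
    beta: float = 0.0
    prior_mean: ReceptiveField | None = None

    def __post_init__(self) -> None:
        if self.kind not in PRIOR_KINDS:
            raise ValueError(f"prior kind must be one of {PRIOR_KINDS}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("prior strengths must be non-negative")
        if self.kind in ("adaptive", "mixed") and self.prior_mean is None:
            raise ValueError(f"{self.kind} prior requires a prior mean")
        if self.kind == "zero_mean":
            self.beta = 0.0
        if self.kind == "adaptive":
            self.alpha = 0.0

    def mean_vector(self, n_dims: int) -> np.ndarray:
        if self.prior_mean is None:
            return np.zeros(n_dims)
        if self.prior_mean.k.size != n_dims:
            raise ValueError("prior mean dimension mismatch")
        return self.prior_mean.k

    def with_strengths(self, alpha: float | None = None,
                       beta: float | None = None) -> "PriorSpec":
        return PriorSpec(
            kind=self.kind,
            alpha=self.alpha if alpha is None else alpha,
            beta=self.beta if beta is None else beta,
            prior_mean=self.prior_mean,
        )


@dataclass
class Partition:
    """Division of the recording into (possibly overlapping) parts.

    ``parts[j]`` is the sorted array of design-row indices belonging to
    part ``j``; ``starts_s[j]`` is the nominal start time of the window.
    """

    t_part_s: float
    t_shift_s: float
    t0_s: float
    parts: list[np.ndarray]
    starts_s: list[float]

    def __post_init__(self) -> None:
        if any(len(p) == 0 for p in self.parts):
            raise ValueError("every part must be nonempty")

    @property
    def n_parts(self) -> int:
        return len(self.parts)


def build_design_matrix(ens: StimulusEnsemble, t_win_s: float) -> LaggedDesign:
    """Lag-embed a stimulus into a design matrix of spectro-temporal patches.

    A row is produced for every bin whose complete ``L``-bin history
    (``L = round(t_win_s / dt_s)``) lies inside a single stimulation
    segment; bins with incomplete history are dropped rather than
    zero-padded.

    Raises
    ------
    ValueError
        If ``t_win_s`` is not a positive multiple of the bin duration, or
        exceeds the length of the shortest segment.
    """
    dt = ens.dt_s
    ratio = t_win_s / dt
    L = int(round(ratio))
    if L < 1 or abs(ratio - L) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"t_win_s={t_win_s} is not a positive multiple of dt_s={dt}"
        )
    for a, b in ens.segments:
        if b - a < L:
            raise ValueError(
                f"lag window of {L} bins exceeds segment ({a}, {b}) "
                f"of length {b - a}"
            )
    F = ens.n_channels
    rows = []
    bins = []
    for a, b in ens.segments:
        # sliding windows within the segment: bins a+L-1 .. b-1
        seg = ens.spec[:, a:b]
        n = b - a - L + 1
        # windows[j] = seg[:, j:j+L]  -> (n, F, L)
        win = np.lib.stride_tricks.sliding_window_view(seg, L, axis=1)
        win = np.transpose(win, (1, 0, 2))  # (n, F, L)
        rows.append(win.reshape(n, F * L))
        bins.append(np.arange(a + L - 1, b))
    S = np.ascontiguousarray(np.concatenate(rows, axis=0), dtype=float)
    row_bins = np.concatenate(bins)
    return LaggedDesign(S=S, row_bins=row_bins, L=L, n_channels=F, dt_s=dt)


def bin_spikes(spike_times_s: Sequence[float], dt_s: float,
               t_total_s: float) -> SpikeTrain:
    """Discretize spike times onto the stimulus time grid.

    Bin ``i`` (0-based) receives a spike iff some spike time falls in
    ``[i*dt, (i+1)*dt)``.  Multiple spikes in one bin collapse to a single
    binary event (with a logged warning); the Bernoulli response model
    requires a binary vector.
    """
    times = np.asarray(list(spike_times_s), dtype=float)
    if times.size and times.min() < 0:
        raise ValueError("negative spike times")
    if times.size and times.max() >= t_total_s:
        raise ValueError("spike times must lie in [0, t_total_s)")
    n_bins = int(round(t_total_s / dt_s))
    r = np.zeros(n_bins, dtype=np.uint8)
    idx = np.floor(times / dt_s).astype(int)
    if idx.size and np.unique(idx).size < idx.size:
        warnings.warn("multiple spikes in one bin collapsed to 1",
                      stacklevel=2)
        logger.warning("multiple spikes in one bin collapsed to 1")
    r[idx] = 1
    return SpikeTrain(r=r, dt_s=dt_s)
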