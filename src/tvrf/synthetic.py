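"""Simulated model cells, stimulus ensembles, and spike generation.

This module provides the generative side of the framework: linear-
nonlinear model cells with (possibly time-varying) Gabor-shaped
spectro-temporal filters, three stimulus families, spectrogram
preprocessing, and Bernoulli spike generation.  Together these emulate
the study conditions under which the estimators are validated:

* ``gaussian_corr`` -- temporally correlated Gaussian noise, the classic
  well-behaved ensemble for linear-Gaussian estimation.
* ``fm_blocks`` -- consecutive 100 ms blocks of four frequency-modulated
  tone trajectories with log-uniform endpoint frequencies in
  0.5-16 kHz, 5 ms half-cosine on/off ramps, 10 s stimuli interleaved
  with 100-1000 ms silences (synthesized directly in the spectrogram
  domain); the long-run spectrum is approximately flat across
  log-spaced channels.
* ``speech_surrogate`` -- a non-Gaussian, sparse, temporally and
  spectrally correlated spectrogram with 1/f modulation spectra and a
  syllable-like on/off envelope, log-compressed; a stand-in for natural
  speech ensembles.

Model cells transform the lag-embedded stimulus ``z = s'k_t`` through a
static logistic nonlinearity into a per-bin spike probability
``p = rate_scale * f(gain * z + b)``; spikes are drawn independently per
bin (at most one spike per bin by construction).  Time variation follows
the ramped-inhibition scheme: the negative coefficients of a base filter
are scaled by a per-part factor while excitatory coefficients stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datamodel import (ReceptiveField, SpikeTrain, StimulusEnsemble,
                        build_design_matrix)

__all__ = [
    "ModelCell",
    "StimulusSpec",
    "gabor_strf",
    "timevarying_cell",
    "gen_stimulus",
    "preprocess",
    "calibrate_cell",
    "calibrate_offset",
    "generate_spikes",
    "simulate_linear_gaussian",
]

STIMULUS_KINDS = ("gaussian_corr", "fm_blocks", "speech_surrogate")


@dataclass
class ModelCell:
    """Linear-nonlinear Bernoulli model cell.

    ``filters`` has shape (P, F, L): one filter per equal-duration part of
    the stimulus (P = 1 for a static cell).  Spike probability per bin is
    ``min(1, rate_scale * logistic(gain * z + b))``.
    """

    filters: np.ndarray
    b: float = 0.0
    gain: float = 1.0
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim == 2:
            self.filters = self.filters[None]
        if self.filters.ndim != 3:
            raise ValueError("filters must have shape (P, F, L) or (F, L)")
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be non-negative")

    @property
    def n_parts(self) -> int:
        return self.filters.shape[0]

    @property
    def n_channels(self) -> int:
        return self.filters.shape[1]

    @property
    def n_lags(self) -> int:
        return self.filters.shape[2]

    def filter_vectors(self) -> np.ndarray:
        """Filters vectorized frequency-major, shape (P, F*L)."""
        P = self.n_parts
        return self.filters.reshape(P, -1)

    def mean_filter(self) -> np.ndarray:
        """Temporal mean of the true filter across parts (F*L vector)."""
        return self.filter_vectors().mean(axis=0)

    def part_of_bins(self, n_bins: int) -> np.ndarray:
        """Assign each stimulus bin to one of the P equal-duration parts."""
        edges = np.linspace(0, n_bins, self.n_parts + 1)
        return np.clip(np.searchsorted(edges, np.arange(n_bins),
                                       side="right") - 1, 0,
                       self.n_parts - 1)


@dataclass
class StimulusSpec:
    """Parameters of one of the synthetic stimulus families."""

    kind: str
    duration_s: float
    dt_s: float = 0.004
    n_channels: int = 15
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValueError(f"kind must be one of {STIMULUS_KINDS}")
        if self.duration_s <= 0 or self.dt_s <= 0 or self.n_channels < 1:
            raise ValueError("invalid stimulus dimensions")


def gabor_strf(F: int, L: int, center_freq_idx: float | None = None,
               center_lag: float | None = None,
               widths: tuple[float, float] | None = None,
               orientation: float = 0.0, amplitude: float = 1.0,
               spatial_freq: float | None = None,
               phase: float = 0.0) -> np.ndarray:
    """Gabor-shaped spectro-temporal filter on an F x L grid.

    A Gaussian envelope centered at ``(center_freq_idx, center_lag)`` is
    modulated by a cosine of frequency ``spatial_freq`` (cycles per bin)
    along the axis rotated by ``orientation`` radians from the frequency
    axis.  ``spatial_freq = 0`` with ``phase = 0`` yields a pure Gaussian
    bump.  At the defaults the excitatory and inhibitory integrals are
    approximately balanced (the carrier's DC leakage is small relative to
    the envelope).

    Returns the (F, L) filter matrix (lag oldest -> most recent).
    """
    if center_freq_idx is None:
        center_freq_idx = (F - 1) / 2.0
    if center_lag is None:
        center_lag = (L - 1) - max(1.0, L / 4.0)  # peak latency ~ T_win/4
    if widths is None:
        widths = (max(1.0, F / 6.0), max(1.0, L / 6.0))
    sig_f, sig_l = widths
    if spatial_freq is None:
        # one flanking inhibitory lobe on each side of the center
        spatial_freq = 0.5 / sig_f
    f_idx, l_idx = np.meshgrid(np.arange(F, dtype=float),
                               np.arange(L, dtype=float), indexing="ij")
    df = f_idx - center_freq_idx
    dl = l_idx - center_lag
    c, s = np.cos(orientation), np.sin(orientation)
    x = c * df + s * dl   # modulated axis
    y = -s * df + c * dl
    env = np.exp(-0.5 * (x / sig_f) ** 2 - 0.5 * (y / sig_l) ** 2)
    carrier = np.cos(2.0 * np.pi * spatial_freq * x + phase)
    return amplitude * env * carrier


def timevarying_cell(base_strf: np.ndarray, inhibition_ramp,
                     b: float = 0.0, gain: float = 1.0,
                     rate_scale: float = 1.0) -> ModelCell:
    """Cell whose inhibitory filter components strengthen over time.

    For each part ``p`` the negative coefficients of ``base_strf`` are
    multiplied by ``inhibition_ramp[p]``; positive coefficients are left
    untouched.  A ramp of all ones yields a static cell.
    """
    base = np.asarray(base_strf, dtype=float)
    if base.ndim != 2:
        raise ValueError("base_strf must be an (F, L) matrix")
    ramp = np.asarray(inhibition_ramp, dtype=float).ravel()
    if np.any(ramp < 0):
        raise ValueError("ramp factors must be non-negative")
    neg = np.minimum(base, 0.0)
    pos = np.maximum(base, 0.0)
    filters = pos[None] + ramp[:, None, None] * neg[None]
    return ModelCell(filters=filters, b=b, gain=gain, rate_scale=rate_scale)


def _log_spaced_freqs(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    return np.geomspace(f_lo, f_hi, n)


def _gen_gaussian_corr(spec: StimulusSpec, rng: np.random.Generator):
    corr_len_s = spec.params.get("corr_len_s", 5 * spec.dt_s)
    n_bins = int(round(spec.duration_s / spec.dt_s))
    F = spec.n_channels
    x = rng.standard_normal((F, n_bins))
    # Gaussian smoothing with sigma = corr_len / (2 dt) gives an
    # autocorrelation of exactly 1/e at lag corr_len
    sigma_bins = corr_len_s / (2.0 * spec.dt_s)
    if sigma_bins > 0:
        x = gaussian_filter1d(x, sigma_bins, axis=1, mode="wrap")
        x /= x.std(axis=1, keepdims=True)
    freqs = _log_spaced_freqs(*spec.params.get("freq_range_hz", (500.0, 8000.0)),
                              F)
    return StimulusEnsemble(spec=x, dt_s=spec.dt_s, freqs_hz=freqs)


def _gen_fm_blocks(spec: StimulusSpec, rng: np.random.Generator):
    """FM tone-complex blocks synthesized in the spectrogram domain.

    ``duration_s`` counts stimulation time (silences come on top).  Each
    10 s stimulus is one segment; silences of 100-1000 ms separate them.
    """
    dt = spec.dt_s
    F = spec.n_channels
    p = spec.params
    f_lo, f_hi = p.get("freq_range_hz", (500.0, 16000.0))
    block_s = p.get("block_s", 0.1)
    tones = p.get("tones_per_block", 4)
    ramp_s = p.get("ramp_s", 0.005)
    stim_s = p.get("stimulus_s", 10.0)
    sil_range = p.get("silence_range_s", (0.1, 1.0))
    # analysis channels sit inside the tone range (the stimulus spectrally
    # encompasses the recorded response area); straight-line FM chords
    # cover the interior of the tone range nearly uniformly, so the
    # long-run spectrum is approximately flat across these channels
    ch_lo, ch_hi = p.get("channel_range_hz", (1000.0, 8000.0))
    freqs = _log_spaced_freqs(ch_lo, ch_hi, F)
    logf = np.log(freqs)
    # spectral spread of a tone across channels, in log-frequency units
    sigma_logf = p.get("sigma_logf", 0.6 * np.median(np.diff(logf)))

    bins_per_block = max(1, int(round(block_s / dt)))
    blocks_per_stim = int(round(stim_s / block_s))
    n_stimuli = max(1, int(round(spec.duration_s / stim_s)))
    ramp_bins = max(1, int(round(ramp_s / dt)))
    ramp = np.sin(0.5 * np.pi * (np.arange(ramp_bins) + 0.5) / ramp_bins) ** 2
    env = np.ones(bins_per_block)
    env[:ramp_bins] = ramp
    env[-ramp_bins:] = ramp[::-1]

    columns = []
    segments = []
    cursor = 0
    for s in range(n_stimuli):
        stim_cols = np.zeros((F, blocks_per_stim * bins_per_block))
        t_block = (np.arange(bins_per_block) + 0.5) / bins_per_block
        for blk in range(blocks_per_stim):
            sl = slice(blk * bins_per_block, (blk + 1) * bins_per_block)
            for _ in range(tones):
                lf0, lf1 = rng.uniform(np.log(f_lo), np.log(f_hi), size=2)
                traj = lf0 + (lf1 - lf0) * t_block  # linear in log-frequency
                # Gaussian deposit in log-frequency channel space
                w = np.exp(-0.5 * ((logf[:, None] - traj[None, :])
                                   / sigma_logf) ** 2)
                stim_cols[:, sl] += w * env[None, :]
        columns.append(stim_cols)
        segments.append((cursor, cursor + stim_cols.shape[1]))
        cursor += stim_cols.shape[1]
        if s < n_stimuli - 1:
            sil_bins = int(round(rng.uniform(*sil_range) / dt))
            columns.append(np.zeros((F, sil_bins)))
            cursor += sil_bins
    return StimulusEnsemble(spec=np.concatenate(columns, axis=1), dt_s=dt,
                            freqs_hz=freqs, segments=segments)


def _gen_speech_surrogate(spec: StimulusSpec, rng: np.random.Generator):
    """Non-Gaussian, sparse, correlated spectrogram surrogate for speech.

    Per-channel Gaussian carriers with a 1/f modulation spectrum are
    mixed with a common component (cross-channel correlation), smoothed
    across neighboring channels, exponentiated to log-normal amplitudes,
    gated by a syllable-like on/off envelope, and log-compressed.  The
    output is standardized per channel.
    """
    dt = spec.dt_s
    F = spec.n_channels
    p = spec.params
    n_bins = int(round(spec.duration_s / dt))
    rho = p.get("channel_corr", 0.6)
    log_sigma = p.get("log_sigma", 1.0)
    syllable_s = p.get("syllable_s", 0.25)
    spectral_smooth = p.get("spectral_smooth", 1.0)

    # modulation spectrum: 1/f-like decay above the syllable rate, flat
    # below it -- speech modulation energy concentrates near a few Hz and
    # the ensemble stays statistically stationary on tens-of-seconds
    # scales (no ultra-slow drift)
    f_corner = p.get("mod_corner_hz", 1.0 / syllable_s / 4.0)

    def one_over_f(shape):
        white = rng.standard_normal(shape)
        Xf = np.fft.rfft(white, axis=-1)
        f = np.fft.rfftfreq(shape[-1], d=dt)
        amp = 1.0 / (f + f_corner)
        amp[0] = 0.0
        x = np.fft.irfft(Xf * amp, n=shape[-1], axis=-1)
        x /= x.std(axis=-1, keepdims=True)
        return x

    common = one_over_f((n_bins,))
    indep = one_over_f((F, n_bins))
    g = np.sqrt(rho) * common[None, :] + np.sqrt(1.0 - rho) * indep
    if spectral_smooth > 0:
        g = gaussian_filter1d(g, spectral_smooth, axis=0, mode="nearest")
        g /= g.std(axis=1, keepdims=True)
    # syllable-like gating: smoothed rectified noise shared across channels,
    # with a small floor (background level) so silences are quiet, not void
    e = gaussian_filter1d(rng.standard_normal(n_bins),
                          syllable_s / dt / 2.0, mode="wrap")
    # voicing_shift sets the speech-activity duty cycle (~80% active for
    # concatenated read speech); the floor keeps pauses quiet, not void
    e = np.maximum(e / e.std() + p.get("voicing_shift", 0.8), 0.0) ** 2
    e += p.get("envelope_floor", 0.05)
    amp = e[None, :] * np.exp(log_sigma * g)
    eps = 1e-5 * amp.max()
    x = np.log(amp + eps)
    # bin-level roughness of real log-spectrograms (keeps patches from
    # becoming collinear during quiet stretches)
    x += p.get("roughness", 0.3) * rng.standard_normal(x.shape)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    freqs = _log_spaced_freqs(*p.get("freq_range_hz", (500.0, 8000.0)), F)
    return StimulusEnsemble(spec=x, dt_s=dt, freqs_hz=freqs)


def gen_stimulus(spec: StimulusSpec) -> StimulusEnsemble:
    """Generate a stimulus ensemble from one of the synthetic families."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "gaussian_corr":
        return _gen_gaussian_corr(spec, rng)
    if spec.kind == "fm_blocks":
        return _gen_fm_blocks(spec, rng)
    return _gen_speech_surrogate(spec, rng)


def preprocess(ens: StimulusEnsemble, fs_target_hz: float,
               compression: str = "log",
               eps: float | None = None) -> StimulusEnsemble:
    """Block-average resample to ``fs_target_hz`` and compress statically.

    Emulates the preprocessing applied to filter-bank magnitudes:
    resampling to the analysis frame rate followed by logarithmic
    compression ``x -> log(x + eps)`` (cochlear dynamic-range emulation).
    ``eps`` defaults to 1e-5 of the maximum magnitude.
    """
    fs_native = 1.0 / ens.dt_s
    if fs_target_hz > fs_native + 1e-9:
        raise ValueError("fs_target must not exceed the native frame rate")
    factor = int(round(fs_native / fs_target_hz))
    if abs(fs_native / fs_target_hz - factor) > 1e-6:
        raise ValueError("fs_target must divide the native frame rate")
    x = ens.spec
    if factor > 1:
        T = (x.shape[1] // factor) * factor
        x = x[:, :T].reshape(x.shape[0], -1, factor).mean(axis=2)
        segments = []
        for a, b in ens.segments:
            a2 = -(-a // factor)  # ceil
            b2 = b // factor
            if b2 > a2:
                segments.append((a2, min(b2, x.shape[1])))
    else:
        segments = list(ens.segments)
    if compression == "log":
        if eps is None:
            eps = 1e-5 * float(np.abs(x).max())
        if eps <= 0:
            raise ValueError("eps must be positive")
        x = np.log(x + eps)
    elif compression is not None and compression != "none":
        raise ValueError(f"unknown compression '{compression}'")
    return StimulusEnsemble(spec=x, dt_s=ens.dt_s * factor,
                            freqs_hz=ens.freqs_hz, segments=segments)


def _spike_probabilities(cell: ModelCell, ens: StimulusEnsemble):
    design = build_design_matrix(ens, cell.n_lags * ens.dt_s)
    kvecs = cell.filter_vectors()
    part = cell.part_of_bins(ens.n_bins)[design.row_bins]
    z = np.einsum("nd,nd->n", design.S, kvecs[part])
    from scipy.special import expit
    p = np.minimum(1.0, cell.rate_scale * expit(cell.gain * z + cell.b))
    return design, p


def calibrate_cell(cell: ModelCell, ens: StimulusEnsemble,
                   target_rate_hz: float = 10.0,
                   target_z_sd: float = 2.0) -> ModelCell:
    """Calibrate gain and offset of a cell against a concrete stimulus.

    The gain is set so the standard deviation of the nonlinearity input
    ``gain * z`` over design rows equals ``target_z_sd`` (the filter
    output variance depends on the stimulus correlation structure, so a
    fixed gain cannot guarantee a useful operating range), then the
    offset is set by bisection to hit ``target_rate_hz``.
    """
    cell.gain = 1.0
    design, _ = _spike_probabilities(cell, ens)
    kvecs = cell.filter_vectors()
    part = cell.part_of_bins(ens.n_bins)[design.row_bins]
    z = np.einsum("nd,nd->n", design.S, kvecs[part])
    sd = float(z.std())
    if sd == 0:
        raise ValueError("filter output is constant on this stimulus")
    cell.gain = target_z_sd / sd
    return calibrate_offset(cell, ens, target_rate_hz)


def calibrate_offset(cell: ModelCell, ens: StimulusEnsemble,
                     target_rate_hz: float = 10.0) -> ModelCell:
    """Set the cell's offset so the mean firing rate matches a target.

    Solves for ``b`` by bisection on the mean per-bin spike probability;
    the default 10 spikes/s comfortably exceeds the 2 spikes/s inclusion
    level used for real units.
    """
    target_p = target_rate_hz * ens.dt_s
    if not 0 < target_p < min(1.0, cell.rate_scale):
        raise ValueError("target rate out of achievable range")
    lo, hi = -50.0, 50.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        cell.b = mid
        _, p = _spike_probabilities(cell, ens)
        if p.mean() < target_p:
            lo = mid
        else:
            hi = mid
    cell.b = 0.5 * (lo + hi)
    return cell


def generate_spikes(cell: ModelCell, ens: StimulusEnsemble,
                    seed: int = 0) -> SpikeTrain:
    """Draw Bernoulli spikes from the cell's per-bin probabilities.

    Probabilities are defined only for bins with a complete lag history
    inside a stimulation segment; all other bins are spike-free.  At most
    one spike per bin by construction.
    """
    design, p = _spike_probabilities(cell, ens)
    rng = np.random.default_rng(seed)
    r = np.zeros(ens.n_bins, dtype=np.uint8)
    r[design.row_bins] = rng.random(p.size) < p
    return SpikeTrain(r=r, dt_s=ens.dt_s)


def simulate_linear_gaussian(S: np.ndarray, k: np.ndarray, sigma: float,
                             seed: int = 0) -> np.ndarray:
    """Continuous response r = S k + eps with Gaussian white noise."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    S = np.asarray(S, dtype=float)
    rng = np.random.default_rng(seed)
    r = S @ np.asarray(k, dtype=float).ravel()
    if sigma > 0:
        r = r + sigma * rng.standard_normal(S.shape[0])
    return r
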