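"""Canned simulation experiments at the package's committed study scales.

These functions implement the flagship simulation protocols end to end
(generate stimulus, simulate the model cell, fit, score) so that scripts
and tests exercise exactly the same conditions.
"""

from __future__ import annotations

import numpy as np

from .datamodel import LaggedDesign, StimulusEnsemble, build_design_matrix
from .evaluation import rf_correlation
from .synthetic import (ModelCell, StimulusSpec, calibrate_cell, gabor_strf,
                        gen_stimulus, generate_spikes, timevarying_cell)
from .timevarying import fit_static

__all__ = ["true_mean_filter_for_rows", "make_speech_cell_recording",
           "static_recovery"]

# flagship conditions: 300 s speech-like surrogate at 250 Hz, 12 channels,
# 60 ms analysis window, inhibition ramping from half to 1.5x balance over
# ten parts, ~20 spikes/s
FLAGSHIP = dict(duration_s=300.0, dt_s=0.004, n_channels=12, n_lags=15,
                ramp=(0.5, 1.5), n_cell_parts=10, rate_hz=20.0, z_sd=3.0)

STATIC_ALPHA_GRID = [(float(a), 0.0) for a in np.logspace(-1, 3, 5)]


def true_mean_filter_for_rows(cell: ModelCell, ens: StimulusEnsemble,
                              design: LaggedDesign,
                              rows: np.ndarray) -> np.ndarray:
    """Mean of the cell's true filter over the bins of the given rows."""
    kv = cell.filter_vectors()
    part = cell.part_of_bins(ens.n_bins)[design.row_bins[rows]]
    return kv[part].mean(axis=0)


def make_speech_cell_recording(seed: int, duration_s=300.0, dt_s=0.004,
                               n_channels=12, n_lags=15, ramp=(0.5, 1.5),
                               n_cell_parts=10, rate_hz=20.0, z_sd=3.0):
    """Speech-surrogate recording of a ramped-inhibition Gabor cell."""
    ens = gen_stimulus(StimulusSpec("speech_surrogate",
                                    duration_s=duration_s, dt_s=dt_s,
                                    n_channels=n_channels, seed=seed))
    base = gabor_strf(n_channels, n_lags)
    cell = timevarying_cell(base, np.linspace(ramp[0], ramp[1],
                                              n_cell_parts))
    cell = calibrate_cell(cell, ens, target_rate_hz=rate_hz,
                          target_z_sd=z_sd)
    spikes = generate_spikes(cell, ens, seed=seed + 1)
    return ens, spikes, cell


def static_recovery(seed: int, n_folds: int = 5, **conditions) -> float:
    """Correlation between the CV-regularized static GLM estimate and the
    temporal mean of the true time-varying filter, at flagship scale."""
    cond = {**FLAGSHIP, **conditions}
    ens, spikes, cell = make_speech_cell_recording(
        seed, duration_s=cond["duration_s"], dt_s=cond["dt_s"],
        n_channels=cond["n_channels"], n_lags=cond["n_lags"],
        ramp=cond["ramp"], n_cell_parts=cond["n_cell_parts"],
        rate_hz=cond["rate_hz"], z_sd=cond["z_sd"])
    t_win = cond["n_lags"] * cond["dt_s"]
    rf = fit_static(ens, spikes, t_win, grid=STATIC_ALPHA_GRID,
                    n_folds=n_folds, seed=seed)
    return rf_correlation(rf.k, cell.mean_filter())
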