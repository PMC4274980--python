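"""Simulate a stimulus-response recording and write the container.

Builds 60 s of speech-like surrogate spectrogram, drives a Gabor-filter
model cell with gradually strengthening inhibition through a logistic
nonlinearity, draws Bernoulli spikes, and writes the HDF5 container.
The printed rate should sit near the 15 spikes/s calibration target.
"""

import numpy as np

from tvrf import (StimulusSpec, calibrate_cell, gabor_strf, gen_stimulus,
                  generate_spikes, timevarying_cell, write_recording)

ens = gen_stimulus(StimulusSpec("speech_surrogate", duration_s=60.0,
                                dt_s=0.005, n_channels=9, seed=1))
base = gabor_strf(9, 12)  # frequency x lag Gabor filter
cell = timevarying_cell(base, inhibition_ramp=np.linspace(0.5, 1.5, 10))
cell = calibrate_cell(cell, ens, target_rate_hz=15.0, target_z_sd=3.0)
spikes = generate_spikes(cell, ens, seed=2)
write_recording("recording.h5", ens, spikes)

print(f"stimulus: {ens.n_channels} channels x {ens.n_bins} bins "
      f"({ens.duration_s:.0f} s at {1 / ens.dt_s:.0f} Hz)")
print(f"spikes:   {spikes.n_spikes} "
      f"({spikes.n_spikes / ens.duration_s:.1f} spikes/s)")
print("wrote recording.h5")
# The cell's inhibitory subfield strengthens 3x across the recording, so
# the true filter drifts over time while the excitatory part stays fixed.
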