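"""Cluster bootstrap local RFs and read out the state timecourse.

Pools all bootstrap local estimates, fits diagonal-covariance Gaussian
mixtures for K = 1..6 with 10 random EM restarts each, picks K by BIC,
and summarizes when each cluster "owns" a part (more than half of the
bootstrap estimates assigned).  Few clusters that persist over
contiguous stretches indicate slow, consistent filter fluctuations;
many one-off clusters indicate unstructured variability.
"""

import numpy as np

from tvrf import (StimulusSpec, build_design_matrix, calibrate_cell,
                  cluster_timecourse, fit_local_sequence, fit_static,
                  gabor_strf, gen_stimulus, generate_spikes,
                  make_partition, select_k_bic, timevarying_cell)

ens = gen_stimulus(StimulusSpec("speech_surrogate", duration_s=60.0,
                                dt_s=0.005, n_channels=7, seed=10))
cell = timevarying_cell(gabor_strf(7, 9), np.linspace(0.3, 1.8, 6))
cell = calibrate_cell(cell, ens, target_rate_hz=20.0, target_z_sd=3.0)
spikes = generate_spikes(cell, ens, seed=11)

design = build_design_matrix(ens, 9 * ens.dt_s)
static = fit_static(ens, spikes, 9 * ens.dt_s,
                    grid=[(a, 0.0) for a in (0.1, 10.0, 1000.0)],
                    seed=1, design=design)
partition = make_partition(ens, 20.0, 5.0, design=design)
n_boot = 10
seq = fit_local_sequence(ens, spikes, static, partition, n_boot=n_boot,
                         seed=2, grid=[(1.0, 1.0), (1.0, 100.0)],
                         reuse_hyperparams=True, design=design)

X = np.array([f.rf.k for fits in seq.locals for f in fits])
model, bic_table = select_k_bic(X, k_range=range(1, 7), restarts=10,
                                seed=3)
labels = model.predict(X).reshape(partition.n_parts, n_boot)
tc = cluster_timecourse(model, labels, partition)

print(f"pooled local estimates: {X.shape[0]} ({partition.n_parts} parts "
      f"x {n_boot} bootstraps)")
print("BIC by K:", {k: round(v) for k, v in bic_table.items()})
print(f"selected K = {model.K}")
for c in range(model.K):
    print(f"  cluster {c}: {tc.occurrences[c]} occurrence(s), "
          f"total extent {tc.extent_s[c]:.0f} s")
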