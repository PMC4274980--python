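# Methods

This note documents the models, estimators, simulation protocols and
numerical choices implemented in `tvrf`, in the spirit of a methods
section: everything a user needs to interpret the outputs and to judge
what the synthetic validations do and do not demonstrate.

## Encoding model

Spiking is modeled per time bin as a Bernoulli draw from a
linear–nonlinear cascade: `p(spike) = f(s'k + b)` with `s` the
vectorized spectro-temporal patch preceding the bin, `k` the receptive
field, `b` an offset and `f` the logistic function. The response vector
is strictly binary; multiple spikes falling into one bin are collapsed
to one with a warning (at the analysis frame rates used here, 250–400
Hz, multi-spike bins are rare for rates below ~30 spikes/s).

Patches are built by lag-embedding the spectrogram: a design row exists
for every bin whose complete `L`-bin history (`L = round(T_win/Δt)`)
lies inside one stimulation segment. Bins with incomplete history are
dropped, not zero-padded — zero-padding would bias onset filters.
Vectorization is frequency-major with lags ordered oldest → most
recent; this convention is fixed so saved filters are portable, and all
estimators are covariant to it.

## Static and local estimation

The **static RF** is the MAP fit of the ridge-penalized (zero-mean
Gaussian prior) Bernoulli GLM on all design rows, with α selected by
stratified 5-fold cross-validation (folds stratified by spike
presence, so every fold carries the global spike fraction; selection
maximizes the mean held-out Bernoulli log-likelihood; ties break toward
stronger regularization — the conservative choice).

**Local RFs** are estimated per part of a sliding partition (defaults
`T_part` = 20 s, `T_shift` = 5 s). Windows are generated while a full
window fits; if data remain beyond the last full window, one trailing
shorter window is appended provided it is at least `T_part/2` long.
Seconds convert to bins by flooring. Each part is re-fit on `n_boot`
= 10 random subsets of 90% of its rows (without replacement), giving
bootstrap spread for the similarity traces. The prior mean is the
static RF; the mixed prior is the default. Hyperparameters are selected
by CV within each bootstrap subsample (nested, so no information leaks
into held-out evaluations); for loops over many parts a `reuse` switch
selects once on the first part and reuses the pair — cheaper, but it
couples the shrinkage level to spike count (see the note on the
cc-vs-spike-count statistic below). Parts with fewer than 5 spikes are
flagged and skipped, never silently dropped.

The offset `b` is never penalized, under either prior: the mean firing
rate must remain fittable even when the filter is pinned to the prior.

The penalized log-likelihood is concave; `fit_map` maximizes it with
scipy's trust-region Newton-CG using the analytic gradient and an exact
Hessian-vector product. Tolerance: gradient infinity-norm ≤ 1e-6, at
most 200 iterations; non-convergence is flagged on the returned fit
rather than raised. With α = β = 0 and separable data the optimum is at
infinity; a guard aborts when the filter norm exceeds 1e2 (a norm
unreachable for any penalized or non-separable problem — note that
beyond margins of ~745 the gradient underflows to zero exactly, so much
larger guard thresholds would never fire).

In the linear-Gaussian model the three priors give closed forms; all
are solved through a Cholesky factorization of the regularized normal
matrix rather than explicit inversion (the stimulus families here are
strongly correlated and the normal matrix is badly conditioned). A
rank-deficient unregularized solve raises with advice to regularize.

## Evaluation

* **cc** between two RF vectors is the normalized inner product
  (cosine similarity), computed on filter coefficients only — offsets
  are excluded.
* The **cc trace** reports per part the mean and standard deviation of
  cc(bootstrap local RF, static RF) plus the part's spike count; the
  Pearson correlation between trace and counts quantifies whether
  apparent filter fluctuations merely track firing rate (a Spearman
  variant is available). Caveat: this statistic is only unbiased when
  hyperparameters adapt per part; with a *fixed* (α, β) the effective
  shrinkage scales like β/n_spikes and the statistic acquires a
  spurious negative component.
* The **prediction protocol** follows repeated random subsampling:
  10% of rows held out (stratified by spike presence), static RF on
  the training rows, local RFs on non-overlapping parts with validation
  rows removed, and a "full" reference model fit on everything. The
  time-dependent Bernoulli log-likelihood evaluates each validation row
  under its part's local parameters; all three log-likelihoods are
  normalized by subtracting the full model's, so normalized(full) ≡ 0
  and positive local values mean the cross-validated time-varying model
  beats the best achievable static fit. Each replicate pairs a fresh
  random split with one part offset t₀ ∈ {0, 5, 10, 15} s (cycling);
  validation rows outside every usable part are excluded from all three
  likelihoods of that replicate, keeping the comparison paired.

## Clustering

Pooled bootstrap local RFs are clustered with a diagonal-covariance
Gaussian mixture (EM via scikit-learn; random-responsibility
initialization, 10 restarts by default, convergence at per-sample
log-likelihood change ≤ 1e-7 or 500 iterations, variance floor 1e-6 of
the mean global variance against component collapse; an effectively
empty component triggers one re-seed before raising). K is selected by
minimizing BIC = −2 log L̂ + d log N with d = K(2D+1) − 1 free
parameters; the full BIC table is returned. The mixture sees no
temporal information — any temporally contiguous cluster occupancy is
a property of the data. The occupancy timecourse assigns a part to a
cluster only when **more than half** of its bootstrap estimates land
there; an occurrence is a maximal contiguous run of such parts and the
extent is the run length × `T_shift`. Full covariances and AIC exist
behind flags but are not defaults (diagonal + BIC was the more robust
combination in our tests; AIC inflates K).

## Synthetic study conditions

The generators define the conditions under which everything is
validated:

* **gaussian_corr** — per-channel Gaussian noise smoothed in time with
  a Gaussian kernel of σ = corr_len/(2Δt) bins, giving an
  autocorrelation of exactly 1/e at the nominal correlation length.
* **fm_blocks** — spectrogram-domain synthesis of 100 ms blocks, four
  frequency-modulated tones per block with endpoints log-uniform in
  0.5–16 kHz and trajectories linear in log-frequency, 5 ms half-cosine
  on/off ramps, 10 s stimuli separated by 100–1000 ms silences (the
  silences become segment gaps, excluded from all analyses). Analysis
  channels default to 1–8 kHz, inside the tone range, where straight
  FM chords cover frequency nearly uniformly and the long-run channel
  spectrum is approximately flat; at the extremes of the tone range the
  chord-coverage density necessarily falls off.
* **speech_surrogate** — a non-Gaussian stand-in for natural-speech
  spectrograms: per-channel Gaussian carriers with a modulation
  spectrum decaying like 1/f above a corner at the syllable rate (flat
  below it, keeping the ensemble stationary on tens-of-seconds scales),
  mixed with a common component and smoothed across channels
  (cross-channel correlation), exponentiated to log-normal amplitudes,
  gated by a syllable-like envelope with ~80% voicing duty cycle and a
  small background floor, log-compressed, bin-level roughness added
  (real log-spectrograms are not smooth at the bin scale; without this
  the design matrix is numerically collinear), and standardized per
  channel.
* **Model cells** use a Gabor-shaped filter on the frequency × lag
  grid; time variation scales the negative (inhibitory) coefficients by
  a per-part ramp while excitatory coefficients stay fixed. Because
  filter-output variance depends on the stimulus correlation structure,
  cells are calibrated against the concrete stimulus: the gain is set
  so the nonlinearity input has a target standard deviation (default
  3.0), then the offset is bisected to a target rate (default 20
  spikes/s ≈ 0.08 spikes per 4 ms bin, comfortably above the 2 spikes/s
  inclusion level used for real units). Spikes are independent
  Bernoulli draws per design bin, at most one per bin by construction.
  All randomness flows from explicit seeds through numpy
  `SeedSequence` spawning; seeded runs are bit-reproducible.

**Flagship simulation** (`tvrf.experiments.static_recovery`, used by
`scripts/acceptance.py`): 300 s of speech surrogate at 250 Hz (Δt =
4 ms), 12 log-spaced channels 0.5–8 kHz, analysis window 60 ms (L = 15;
the simulated Gabor spans ~50 ms — the longer 100 ms window used for
cortical recordings would only add unused dimensions here), inhibition
ramp 0.5 → 1.5 across ten parts (sidelobes grow from half to 1.5× the
balanced level; the temporal mean equals the balanced Gabor), CV over
five log-spaced α values 1e-1…1e3, five seeds.

## What the synthetic validations do and do not show

The surrogate reproduces the gross statistics of speech spectrograms
(sparsity, temporal and spectral correlation, non-Gaussian amplitude
structure) but not its phonetic micro-structure (formant tracks,
harmonic stacks). One consequence is quantitative: fitting a *static*
GLM to a cell whose filter varies over time is a misspecified model,
and the asymptotic bias of that fit depends on the stimulus's
higher-order statistics. On our surrogate the static estimate of the
ramped-inhibition cell correlates ~0.84 with the temporal mean of the
true filter (it reaches 0.95–0.99 for a static cell on the same
stimulus, and ~0.98 for the same time-varying cell on a correlated
Gaussian ensemble); the shortfall is bias, not noise — tripling the
spike count moves it only a few points. Recovery numbers on this
surrogate are therefore conservative relative to smoother natural
ensembles.

Similarly, the mixed prior's advantage over the purely adaptive prior
in tracking a time-varying filter is small by nature; at the desk
scales used in the test suite (40 s recordings, 54 paired conditions)
CV usually selects an adaptive-boundary point of the mixed grid and the
two estimators coincide, so the paired comparison is a tie rather than
a systematic win. The corresponding linear-model property (mismatched
prior, 20 replicates) does separate the estimators and is part of the
test suite.

## Problem sizes in the test suite

Unit tests use toy matrices (tens of rows). Simulation-backed tests
use 30–120 s recordings at 200 Hz with 6–9 channels and 8–12 lags
(design dimensions 48–108), coarse hyperparameter grids (2–5 points per
axis), and 1–10 bootstrap replicates — chosen so the full suite runs in
minutes while each scientific property remains measurable at its scale.
The flagship 300 s × 180-dimensional fit appears once in the acceptance
test and five times (seeds) in `scripts/acceptance.py`.

## Known limitations

* No post-spike history or coupling filters: the GLM here is a pure
  stimulus-driven LN-Bernoulli model.
* Isotropic priors only; smoothness, Laplace or localized priors are
  out of scope.
* Partition-based locality: temporal resolution is set by `T_part`
  (about 10 s is the practical floor); state-space models would be the
  alternative for faster dynamics.
* The prediction protocol's normalization compares against a full
  *static* model; it quantifies the value of time-varying structure,
  not absolute goodness of fit.
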