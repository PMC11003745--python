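# Methods

`lfpstates` analyzes dual-site local field potential (LFP) recordings —
prefrontal cortex (PFC) and hippocampus (HPC) plus one EMG channel — across
the rodent sleep-wake cycle, and ships a ground-truthed synthetic cohort
generator so that every estimator can be validated by parameter recovery
rather than by eye. This note documents the models, the estimator
conventions, the generator's assumptions, and the design choices that were
genuinely open.

## Signal model of the synthetic cohort

Each subject is a three-channel recording at 500 Hz (the package accepts any
rate ≥ 500 Hz; 500 Hz keeps desk-scale validation fast while leaving the
100-200 Hz EMG band and the 0.5-200 Hz comodulogram range below Nyquist).
Brain state follows a first-order Markov chain over {ACT, QWK, NREM, REM} on
a 5 s grid. The default transition matrix is flow-balanced for a stationary
occupancy of roughly 25 / 15 / 45 / 15 % with mean dwell times of about
125 / 40 / 150 / 60 s — ordinary rodent polysomnography numbers. For cohort
subjects the draw is rejected (deterministically, from the same stream)
until every state survives modal consolidation onto the 30 s grid with at
least three epochs, since downstream per-state estimates are undefined
otherwise.

Within a state, each LFP channel is the sum of:

* a 1/f^chi Gaussian background (spectrally shaped noise; chi is the
  aperiodic exponent, flat below 0.5 Hz), per region;
* narrow-band oscillators as filtered noise, never sinusoids: delta
  (~2 Hz), low gamma (~47 Hz), high gamma (~82 Hz) with Gaussian spectral
  profiles, and theta (4.5-11 Hz) with a flat-top (supergaussian) profile so
  that coherence and band power are uniform across the analysis band;
* a theta amplitude envelope: a slowly varying lognormal modulator
  (CV 0.8, ~0.7 Hz bandwidth) shared — lagged — between the HPC theta and
  the independent PFC theta component, so theta power waxes and wanes
  jointly across the loop and the coherence stays stationary;
* EMG as white noise with state-dependent variance.

**Directed coupling.** The PFC theta band is built as a lagged, scaled copy
of the HPC theta component plus independent theta-band noise. The mixing
ratio is solved per synthesis block so that the band-average
magnitude-squared coherence — including the PFC background power that falls
inside 4.5-11 Hz — equals the planted target. The lag (default 40 ms, HPC
leading) is applied as a circular shift within each stationary block.

**Theta-gamma coupling.** The comodulogram measures Pearson correlation
between per-frame STFT magnitudes. For Gaussian carriers each bin magnitude
carries irreducible Rayleigh fluctuation, which attenuates any planted
envelope correlation; a generator that naively set the envelope correlation
to r would always under-deliver. The planted `coupling_r` is therefore
defined as the target of the *measured* block correlation: the generator
derives the required internal envelope correlation from the Rayleigh-moment
attenuation of the gamma readout (`corr(mR, m)` for lognormal m times an
independent Rayleigh factor) and a fixed theta-readout constant (0.65)
accounting for frame-windowing loss; the high-gamma envelope is then a
lognormal (CV 1.0, clipped at 5 to bound spectral splash) driven by the
frame-scale theta magnitude. Recovery tests hold the planted value to
±0.15.

**Spike-wave discharges (SWDs)** are additive transients: a harmonic stack
(f0 = 7.5 Hz with 2f0 and 3f0 partials) sharpened by cubic waveshaping and
Tukey-tapered, scaled to 5 times the local PFC RMS (half of that added to
HPC). Durations are Gaussian with mean 6.614 s and SD 0.283 s (the SD
implied by the reported 4.281 % coefficient of variation). Events are
placed by per-state rates (defaults: NREM 0.5/min, QWK 0.1, ACT 0.05,
REM 0), entirely inside same-state runs, non-overlapping, and away from the
recording edges. In the ELS preset 44.5 % of subjects express SWDs at all.

**Group presets.** `CTRL` and `ELS` differ only in effect *directions*
reported for early-life-seizure animals, with magnitudes chosen once as
generator knobs: ELS has 1.3x higher ACT HPC theta amplitude, a flatter PFC
spectrum (exponent 1.2 vs 1.5), lower REM theta coherence (0.45 vs 0.60), a
flatter coherence profile across REM/QWK/ACT (raising its entropy), weaker
theta-high-gamma coupling (0.1 vs 0.5 in wake), SWD expression, and
"REM-like ACT": each 30 s ACT block has probability 0.4 of drawing the REM
spectral recipe while keeping awake EMG. Per-subject biological variability
is a small jitter on theta amplitudes (lognormal sd 0.08), exponents
(±0.05), coherence targets (±0.03), coupling (±0.05) and EMG variance.

What the generator does **not** emulate: movement and electrode artifacts,
gradual state transitions (switches are abrupt on the 5 s grid),
non-stationarity across the recording (circadian drift), volume conduction,
and any within-state temporal structure beyond the amplitude envelopes.
Passing recovery tests therefore demonstrates estimator correctness under
the stated statistical structure, not robustness to real-world artifacts.

## Estimator conventions

* **Welch PSD / coherence**: 1 s Hamming segments, 50 % overlap, zero-padded
  to a 0.5 Hz grid (band edges such as 4.5 or 55 Hz then fall on bin
  centers); band membership is by bin center, edges inclusive. Spectral
  analysis runs on 3 s epochs (ten per 30 s hypnogram epoch); per-state
  estimates average epoch-level spectra, matching the per-epoch relative
  power normalization (sum to 1 within 0.5-55 Hz). Note the five
  half-overlapped segments of a 3 s epoch give the magnitude-squared
  coherence a small-sample upward bias at low coherence (~(1-C)^2/5);
  planted-value recovery is asserted within ±0.1, which absorbs it.
* **Fisher z for squared coherence**: z = atanh(sqrt(C)).
* **Staging features**: multitaper (4 DPSS tapers, NW 2.5) band power per
  non-overlapping 5 s epoch; HPC theta 4.5-12, PFC delta 0.7-4, EMG 100-200
  Hz. Staging theta (4.5-12) and comparison theta (4.5-11) are deliberately
  distinct named constants. The theta/delta ratio is HPC theta over PFC
  delta.
* **Staging cascade**: three binary RBF-SVMs on single log-scaled,
  standardized features (EMG for wake/sleep; theta/delta for REM/NREM among
  sleep and ACT/QWK among wake). Bootstrap seed labels come from
  two-component 1-D Gaussian-mixture splits rather than fixed extreme
  quartiles: quartile seeding structurally mislabels whenever a class holds
  less than a quartile of its pool (wake fraction below 25 % of a
  recording, or REM below 25 % of sleep), which we observed directly.
  Stages 2 and 3 re-derive their seeds from the *predicted* sleep and wake
  pools. Consolidation to 30 s takes the modal label of six 5 s epochs,
  ties broken by summed classifier margin.
* **Persistent episodes** are runs of at least 15 s (three 5 s epochs); the
  threshold is configurable because thresholds shorter than one 5 s staging
  epoch are not resolvable on this grid.
* **SWD detection**: STFT magnitude, 250 ms windows, 50 % overlap, per-window
  mean removal (otherwise DC leakage dominates the 3-4 Hz edge). Frame
  score = unweighted mean of the mean magnitudes in 4.4-16.4, 17.6-32.8 and
  35.1-55 Hz; events seed above mean + 1.5 SD, grow to mean + 1 SD.
  "Frame" here is one STFT hop (125 ms): thresholding at staging-epoch
  resolution could not bound ~6 s events to sub-second accuracy. The
  statistics are computed on the band-averaged score (a per-band switch is
  provided). Expert curation is replaced by explicit rules: minimum
  duration 1 s, at least 5 cycles of the dominant frequency, and a
  second-harmonic/fundamental magnitude ratio of at least 0.45 — sustained
  normal theta also crosses an amplitude threshold but is near-sinusoidal
  (ratio ≤ ~0.35 in validation), while the spike-like SWD morphology gives
  ratios ≥ ~0.6.
* **Comodulogram**: 100 ms Hamming frames, 50 % overlap, inside 3 s epochs,
  zero-padded to 0.5 Hz bins over 0.5-200 Hz; frames pooled per
  subject/state before the Pearson matrix (per-epoch averaging is
  available); theta-gamma feature = mean over the (4.5-11) x (65-100) Hz
  block.
* **Cross-correlation**: 50 Hz low-passed epochs, ±1 s lags, normalized by
  the zero-lag autocorrelation geometric mean; negative lag = HPC precedes
  PFC; subject correlogram = mean over epochs; the reported peak is the
  maximum inside [-80, -20] ms.
* **State map**: ratio1 = 4.5-9/4.5-50 Hz, ratio2 = 2-20/2-50 Hz per region
  per 3 s spectral epoch; one SVD per ratio across the two regions (series
  centered but *not* variance-scaled by default — the fixed IS speed
  threshold of 0.1 is only meaningful on the power-ratio scale; a z-scoring
  switch exists); sign fixed by positive correlation with the HPC series;
  unit-sum 10-epoch Hann smoothing with reflect padding. Building the map
  on the 3 s grid matches the source method's smoothing span (10 spectral
  epochs ≈ 30 s); on the 30 s grid the same kernel would span 5 min and
  smear across typical state runs. Epochs faster than 0.1 map units per
  step are flagged intermediate (IS) and excluded from the REM-ACT distance
  and decoding by default (with fallbacks when exclusion would empty a
  state).
* **Cluster validation**: 3-component full-covariance Gaussian mixture
  (k-means init, three restarts, fixed seed); epochs below 0.8 posterior
  stay unassigned; correspondence = chi-squared of cluster x
  {awake, NREM, REM} plus majority-state purity; poor correspondence raises
  a QC flag, never a silent exclusion.
* **Decoding**: one model per experimental group over that group's pooled
  REM/ACT epochs; linear SVM, RBF SVM, and a 50-tree bagged random forest,
  at library-default regularization (no hyperparameter search). AUC-ROC
  with a 1000-repetition case-resampling bootstrap CI (degenerate resamples
  redrawn and counted); high-dimensional (and comparison) decoders use 100
  stratified 80/20 holdout repeats. The whole-spectrum decoder sees
  1-55 Hz PFC power, HPC power and coherence at 0.5 Hz spacing per 30 s
  epoch.
* **Spectral parametrization**: log10-power model b - chi*log10 f plus up
  to four Gaussians over 3-40 Hz, knee-free, minimum peak height 0.05. The
  fit alternates robust aperiodic estimation (positive residuals masked)
  with tallest-first Gaussian extraction and a joint bounded refinement,
  iterated to convergence — a single pass leaves the aperiodic estimate
  biased by whatever peaks its first flattening missed. Oscillatory theta
  power sums peak heights (areas available by switch).
* **Coherence entropy**: H = -sum p_i ln p_i over the normalized mean theta
  coherences of REM/QWK/ACT; in [0, ln 3]; scale-invariant.
* **Fingerprint**: per subject — (1) HPC theta relative power in ACT,
  (2) theta-coherence entropy, (3) PFC aperiodic exponent in ACT, (4) PFC
  theta-high-gamma correlation in ACT, (5) REM theta coherence (Fisher z),
  (6) REM-ACT map distance. Multivariate analyses z-score columns; PCA by
  SVD; the group classifier is a shrinkage-regularized LDA (gamma = 0.1, a
  conventional small value since "regularized" was unquantified) on the
  first two PCs, with z-scoring and PCA refit inside every leave-one-out
  fold to avoid leakage. Univariate AUCs come from single-feature logistic
  regressions, oriented to ≥ 0.5 (equivalent to the rank AUC). Ward
  clustering uses Euclidean distance for subjects and correlation distance
  for variables, with the cluster count chosen by maximum mean silhouette.

## Problem sizes

Validation runs at desk scale: recovery experiments use single 30 min
subjects; the staging benchmark uses one 2 h subject; cohort-level claims
(fingerprint discrimination, REM-ACT distance direction, decoding gaps) use
twenty independent cohorts of 6 CTRL + 9 ELS subjects at 25 min each in the
test suite and eight such cohorts in the acceptance script. These sizes
were chosen so that each estimate's sampling error is well inside the
asserted tolerance.

## Known limitations

* The measured coherence inherits the 5-segment estimator bias, so planted
  low-coherence states read ~0.1-0.2 high; group contrasts are designed on
  the measured scale.
* Strong SWDs contaminate staging of the epochs they occupy (high broadband
  power resembles wake/REM); on SWD-positive synthetic subjects this costs
  a few percent of 5 s epochs. Any EMG/theta-delta staging scheme shares
  this exposure unless discharge epochs are masked first.
* The GMM cluster validation assumes three dominant clusters; recordings
  where a state is nearly absent trip the QC flag by design.
* Exponent estimates on full recordings carry a small positive bias
  (~+0.05) from oscillator tails inside 3-40 Hz; group separation is an
  order of magnitude larger.
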