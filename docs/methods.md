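# Methods

## The classification problem

Three groups walk over a force plate: healthy controls, diabetic-neuropathy
(DN) patients, and DN patients with a healed plantar ulcer (DFU). Each trial
yields six synchronized 1000 Hz channels — EMG of GL, VL, TA and the GRF
components GRFx (anterior–posterior shear), GRFy (mediolateral shear), GRFz
(vertical). The pipeline classifies individual gait cycles into the three
groups from features of these signals, with evaluation that respects subject
identity.

## Synthetic cohort model

The generator produces cohorts with the statistical structure the analysis
assumes, built around the two class effects consistently reported for
diabetic gait:

* **EMG.** Each muscle cycle is `carrier × envelope + noise`. The carrier is
  white noise band-passed 25–499 Hz and scaled to unit RMS (so preprocessing
  is non-degenerate); the envelope is a non-negative Gaussian bump. For
  controls the bump is centered at 45% of the gait cycle — late stance, the
  push-off burst of the calf and thigh muscles — with σ = 80 ms. The DN and
  DFU classes delay the center by `dn_peak_delay` (60 ms) and
  `dfu_peak_delay` (100 ms).
* **GRF.** Stance occupies the first ~60% of the cycle (`[0.01, 0.61]` of its
  duration); the plate reads zero during swing. GRFz is the classic M-shaped
  double hump (centers at 30%/70% of stance, σ = 10% of stance, endpoint-line
  corrected so the noiseless curve is exactly zero at foot strike and
  toe-off). For DN and DFU the second (push-off) hump is scaled by
  `1 − second_peak_reduction` (default 0.15). GRFx is a low-amplitude
  antisymmetric braking/propulsion curve, GRFy a small mediolateral shear;
  both exist only during stance.
* **Subject random effects**, shared by all of a subject's cycles: a Gaussian
  shift of the activation-peak time (`subject_sd`, default 10 ms) and a
  log-normal amplitude factor (`subject_amp_sd`, default 0.15 log-units).
  These induce the within-subject correlation that makes subject-wise
  cross-validation genuinely harder than record-wise. Per-cycle timing jitter
  (`cycle_jitter_sd`, 5 ms) and additive amplitude noise (`noise_sd`, 5% of
  the subject's amplitude) provide record-level variability.

Defaults mirror the emulated study: 6/6/9 subjects, 20 cycles per subject
(the per-subject cycle count is a free parameter of the design), 1 s cycles
at 1000 Hz.

**Why the stance/envelope geometry matters.** The 19-feature EMG bank is
amplitude-statistical: it cannot see *where* in a window a burst occurs, only
how the amplitude is distributed. A timing effect becomes visible to it only
through the stance-locked segmentation: because the control burst peaks just
before toe-off, the class delays push a progressively larger fraction of the
burst past the end of stance, lowering the activity captured in the segment.
An earlier design with stance spanning the whole recording left the timing
effect invisible to every registered feature (a linear-discriminant ceiling
near chance for DN vs DFU); the stance-truncation geometry is what makes the
configured effects recoverable, and it reflects the actual clinical
observation — delayed push-off activation spilling into swing.

**What the generator does not emulate.** Real EMG has muscle-specific
spectra, motion artifacts, crosstalk, and multi-burst activation patterns;
real GRF curves vary in stance duration and shape beyond two humps; DN and
DFU differ in many more dimensions than the two modeled effects. In
particular, the two patient groups share the same GRF effect by
construction, so GRF-only configurations can separate controls from patients
but DN from DFU only at chance — passing tests demonstrate pipeline
correctness and recoverability of the modeled effects, not clinical
performance on real data.

## Preprocessing

* EMG: full-wave rectification, then a zero-phase band-pass 25–499 Hz
  (4th-order Butterworth) cascaded with 60 Hz harmonic notches (2nd-order,
  Q = 30, at 60…480 Hz). Zero phase is realized by applying the cascade's
  *squared magnitude response* on an even (mirror) signal extension — the
  exact forward-backward filter. A time-domain `filtfilt` realization is
  numerically asymmetric here because the 499 Hz corner sits at 99.8% of
  Nyquist; the frequency-domain form is reversal-symmetric to machine
  precision and has identical (squared) attenuation.
* GRF: zero-phase low-pass at 100 Hz via `sosfiltfilt` with even-extension
  padding of up to one second (scipy's default padding is far too short for
  signals with nonzero boundary means).
* Segmentation: stance intervals are maximal runs where the filtered GRFz
  exceeds 5% of its per-recording maximum for ≥ 50 ms; intervals are 0-based
  half-open `[start, end)`. The screen accepts intervals of 0.3–1.5 s with a
  positive peak (an automatic stand-in for the study's semi-manual screening).
* Normalization: EMG segments are divided by the rectified mean of the whole
  trial — the standard amplitude normalization in gait EMG, and the choice
  that preserves the absolute activity reduction caused by burst truncation
  (dividing a segment by its own mean would erase it, and the band-passed
  EMG segment mean is ~0 anyway). GRFz is divided by its segment mean
  (`normalize_by_mean`, output mean exactly 1); the bipolar shear components
  GRFx/GRFy by their segment rectified mean.

## Feature banks

* **EMG (19):** LMAV = ln(mean |x|); NSV = (mean |x|³)^(1/3) (v-order
  statistic, v = 3); WL = Σ|Δx|; WAMP/ZC/SSC with thresholds
  θ_wamp = 0.05, θ_zc = θ_ssc = 0 on normalized signals; Hjorth mobility and
  complexity (variance-degenerate cases map to 0); population skewness;
  Yule-Walker AR(4) (sign convention `x_t ≈ Σ AR_k x_{t−k}`, biased
  autocorrelation without demeaning); m0/m2/m4/m6 as sums of squared
  0th–3rd differences (Parseval surrogates of even spectral moments);
  AC1/AC2 = mean |Δx|, mean |Δ²x|. Each formula is registered once and the
  vector is a composition of the standalone ops.
* **GRF time domain (50):** the 19 above (a constant segment maps its AR
  slots to 0 — a flat plateau is a legal stance shape) plus 31 registered
  amplitude/shape/timing statistics (extrema, percentiles, IQR, RMS,
  variance, kurtosis, first/second peak heights and their time fractions,
  peak ratio, inter-peak valley, integrals, slope statistics, crest factor,
  time-above-half-maximum). Peak times are expressed as fractions of segment
  length so variable-length stances are comparable.
* **GRF frequency domain (24):** Hann-window periodogram statistics (DC bin
  excluded): peak/mean/median frequency, total power, 2nd/3rd spectral
  moments, spread/skew/kurtosis, spectral entropy, flatness, 85%/95%
  roll-off, six band-power fractions (0–5, 5–10, 10–20, 20–50, 50–100,
  100–Nyquist Hz; the top band includes Nyquist so fractions sum to 1),
  low/high power ratio, peak power (absolute and fractional), spectral
  crest, mean power.
* **GRF time–frequency domain (121):** 8-level db4 DWT in periodization mode
  after symmetric end-padding to a multiple of 2⁸, which makes the transform
  exactly orthogonal — sub-band energies of D1–D8 + cA8 partition the
  (padded) signal energy, and reconstruction is exact. The 13 bands are the
  detail coefficients D1–D8, their concatenation cD, the approximation
  reconstructions A6–A8, and the level-8 approximation coefficients cA8.
  Nine statistics per band (energy, log-energy, mean |c|, SD, energy
  entropy, max |c|, coefficient waveform length, zero crossings, relative
  energy within the orthogonal partition) plus four global features (total
  energy, detail/approximation ratio, entropy over the 13 relative energies,
  index of the maximum-energy band) give 9 × 13 + 4 = 121.

The exact feature registries are a documented reconstruction constrained by
the bank sizes (19; 50 + 24 + 121 = 195 per component; 38/57 and 390/585 for
channel combinations); they are the single source of truth and swappable
without touching callers.

## Selection

Correlation pruning scans column pairs in input order and drops the later
column of any pair with |Pearson r| > 0.9 (idempotent, order-deterministic;
zero-variance columns are retained and flagged). Pruning runs *before*
ranking by default so it cannot bias the rankers; the reverse order is
available (`prune_first=False`) for reproduction experiments.

* **chi-square:** features discretized into 10 equal-frequency bins; the
  statistic of the bin × class contingency table (no continuity correction).
* **mRMR:** greedy MID criterion — mutual information with the labels minus
  mean MI with already-selected features, MI estimated from the same
  equal-frequency binning (natural log); full ordering returned.
* **ReliefF:** k = 10 nearest hits and misses per sample (Manhattan distance
  on range-scaled features), miss contributions weighted by class prior over
  `1 − P(own class)`.
* **NCA:** per-feature weights maximizing the expected soft leave-one-out
  nearest-neighbor accuracy (exponential kernel on the weighted Manhattan
  distance with w² weights) minus λ‖w‖², λ = 1/n by default, features
  standardized internally, ranked by squared weight. The smooth objective is
  optimized with L-BFGS from an all-ones start (deterministic; a fixed-step
  gradient ascent was the obvious alternative but is fragile across λ
  scales, e.g. the large-λ shrinkage limit).

Ties everywhere break by input column order. The reported mRMR scores are
the greedy criterion values at selection time and are not guaranteed
monotone, unlike the sort-based rankers.

## Classification and validation

* **Folds:** subjects are shuffled within class and dealt round-robin to 5
  folds (class-stratified, running offset keeps sizes 4–5 for 21 subjects);
  every record of a subject shares its fold. Record-wise folds exist solely
  for the leakage demonstration.
* **Per fold:** features are z-scored with training-fold statistics (a
  Euclidean KNN is meaningless across scales spanning orders of magnitude,
  and fitting scalers on the test fold would leak); the scaled training set
  is SMOTE-balanced to the majority class (interpolation `x + u(x_nn − x)`
  toward one of k = 5 same-class neighbors, k clamped with a warning for
  tiny classes); the KNN predicts the held-out records. Predictions are
  pooled over folds.
* **KNN:** 1 neighbor, Euclidean, squared-inverse weighting (the tuned
  operating point; an exhaustive grid over k ∈ {1,3,5,7,9}, Euclidean/
  cityblock, uniform/inverse/squared-inverse is provided in
  `grid_search_knn` as the deterministic replacement for Bayesian
  optimization). With k = 1 vote weighting is inert, so ROC scores are built
  from the distance to the nearest training point of each class
  (squared-inverse, normalized) to keep the ROC non-degenerate.
* **Incremental search:** evaluate the top-k prefix for k = 1…len(ranking)
  (cappable); best k is the smallest k attaining maximal pooled accuracy.
  Because the maximum of noisy per-k accuracies is optimistically biased
  (clearly visible on null cohorts), `evaluate_config` re-measures the
  selected configuration on a fresh subject-wise split; reported accuracies
  come from that second split.
* **Leakage checks** are machine-enforced in every CV execution: train/test
  record and subject disjointness is asserted per fold, and SMOTE only ever
  receives training rows.

## Evaluation

Per class one-vs-rest: sensitivity TP/(TP+FN), precision TP/(TP+FP),
F1 = 2TP/(2TP+FP+FN); macro values are unweighted class means; accuracy is
trace/total. Metrics are percentages, rounded to two decimals in reports.
AUC is computed per class from the rank statistic (equivalent to the
trapezoidal ROC area with tie averaging) and macro-averaged; degenerate
constant scores yield 0.5 with a warning. An empty test class gets
sensitivity 0 with a warning. The channel experiment enumerates the 7 combos
per modality (3 singles, 3 pairs, 1 triple) × 4 rankers and tabulates combo,
ranker, best top-k and the pooled metrics.

## Problem sizes

Tests and the acceptance script run the full default cohort (21 subjects ×
20 cycles = 420 records) for pipeline-level checks, with the incremental
search capped at the top 10 features for EMG configurations and 20 for GRF;
multi-seed suites (null-cohort calibration, leakage demonstration) use 10–20
seeds. Property fuzzing uses dozens of randomized segments per bank. These
sizes are the package's desk-scale defaults; all scale linearly if enlarged.

## Known limitations

* The two patient classes are distinguishable only through the EMG timing
  effect; GRF-only configurations top out near 67% three-class accuracy by
  design (controls separate cleanly, DN/DFU are exchangeable in GRF).
* The EMG record-level signal rides on a stochastic carrier, so per-record
  feature noise is irreducible (~10% CV for energy statistics); cohorts with
  unlucky subject draws can dip a few points below the typical ~93–96%
  two-muscle accuracy.
* The null-cohort pipeline accuracy sits ~3–4 points above the naive 33.3%
  because top-k selection correlates with the cohort realization even when
  evaluated on a fresh split, and the class imbalance (9 DFU subjects) gives
  the majority class slightly more neighborhood coverage; both effects are
  properties of the evaluation design, not class signal.
* Quality screening is a fixed automatic rule standing in for semi-manual
  curation; no time-normalization of cycles to 0–100% gait is performed
  (features operate on raw-length stance segments).
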