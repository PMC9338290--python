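# Methods

`wearbp` implements a cuffless blood-pressure (BP) estimation pipeline of the
kind used to validate multiparametric wearables: simultaneously recorded ECG,
heart sounds (phonocardiogram, PCG) and thoracic impedance are reduced to
per-observation features, combined with demographics, and fed to seeded
tree-ensemble regressors for systolic and diastolic pressure (SBP/DBP).
Because clinical recordings of this kind are not publicly available, the
package ships a synthetic-study generator with exactly known ground truth;
every downstream stage is validated against that ground truth.

## The estimation problem

A manual dual-observer sphygmomanometer provides reference readings y_i
while the wearable records continuously.  The model produces estimates p_i
from a 60-s window of signals preceding each reading.  Performance is
summarised by

- MAD  = (1/n) Σ |p_i − y_i|            (mmHg)
- MAPD = (1/n) Σ 100·|p_i − y_i| / y_i  (%)
- RMSE = sqrt((1/n) Σ (p_i − y_i)²)     (mmHg)

reported overall and per protocol condition, together with Bland–Altman
agreement (mean difference, SD, mean ± 1.96·SD limits) and Pearson
correlation on the held-out test split.

The scientific question the evaluation machinery answers is whether the
wearable's signals add information beyond demographics.  A demographics-only
baseline (age, sex, height, weight) is trained with identical procedure and
hyperparameters; a paired bootstrap (10,000 resamples, each of test-set
size, the *same* indices applied to both models) yields the distribution of
the RMSE difference (signal model − baseline).  The signal model is declared
superior when the upper bound of the 95% percentile CI of that difference is
below 0 mmHg; the p-value is the fraction of resamples with a difference
≥ 0, floored at 1/n_resamples.  Pairing the draws is the variance-correct
way to compare two models evaluated on the same observations: the shared
sampling noise cancels in the difference.

## Reference-measurement rules

- Two observers read one cuff through a Y-connector; readings are recorded
  to the nearest 2 mmHg.  If they differ by ≤ 4 mmHg the mean is the
  reference; otherwise the measurement is retaken.  The mean of two even
  readings may be odd and is deliberately kept unrounded (the grid applies
  to raw readings, not derived quantities).
- Entry BP is the mean of three seated readings and determines the JNC-7
  class: Normal (SBP < 120 **and** DBP < 80), Prehypertension (120–139 or
  80–89), Stage 1 (140–160 or 90–100), Stage 2 (≥ 160 or ≥ 100).  The
  overlapping boundaries (160, 100) resolve to the higher class, and the
  highest class whose criterion is met wins — so classification is monotone
  in both arguments.
- A sequential device (the wrist-cuff column) is scored against the mean of
  the two references bracketing it in time (the ISO 81060-2:2019
  adjacent-mean rule); simultaneous devices are scored against the
  same-time reference.

## Data preparation

Each recording is screened second by second.  A second is unacceptable on
any of: amplitude saturation (≥ 50 consecutive constant samples at ≥ 99% of
the channel's peak magnitude — ADC-clipping semantics), flatline (variance
below 1e-10; applied to ECG and impedance channels — the PCG is legitimately
near-silent between heart sounds and the activity channel is near-zero at
rest), movement (activity channel above threshold), or an implausible local
RR interval (outside 0.3–2.0 s) on the primary ECG.  Bad data is excluded,
never repaired.

Each reference observation is associated with the **latest** fully
acceptable 60-s window inside the 300-s lookback preceding its timestamp
(half-open [start, start+60), 1-s mask granularity, candidates anchored at
the timestamp and stepped back 1 s at a time).  A lookback reaching before
the start of the recording is truncated.  Observations with no acceptable
window are rejected with a logged reason.  A "centered" mode (window centre
closest to the timestamp, allowed to extend up to 30 s past it) is available
via config for sensitivity analyses; "preceding" is the default because the
data-preparation rule is stated that way, even though ensemble averaging is
sometimes described as centred on the measurement.

Prepared observations are split 80/20 into train/test with
train = floor(0.8·n) by a seeded uniform permutation at observation level
(a subject-level split mode exists for leakage experiments).

## Feature extraction

All features are computed on the 60-s window:

- **R peaks** — band-pass 5–25 Hz, differentiate, square, 150-ms
  moving-window integration, adaptive threshold (25% of the 99th percentile)
  with a 250-ms refractory period; candidates are refined to the extremum of
  the 30-ms-smoothed raw ECG.  RR intervals outside 0.3–2.0 s are screened
  out; fewer than 5 beats rejects the window.
- **Ensemble averaging** — beats aligned at R over one median RR (frame 20%
  before R to 80% after), outlier beats with correlation < 0.5 to the
  running mean excluded (two passes), pointwise mean of the survivors.
  Averaging n beats reduces independent noise by √n.
- **Heart sounds** — on the ensemble-averaged PCG (20–240 Hz), the amplitude
  envelope (analytic magnitude, 11-ms smoothing) is searched for S1 in
  (0, 0.18·RR] after R and S2 in (0.18·RR, 0.6·RR].  Sound times are the
  envelope peaks (giving the R→S1 and R→S2 systolic time intervals); RMS
  amplitudes are taken over ±40 ms.  A region whose best peak is below the
  noise floor (3× envelope median, and ≥ 5% of the strongest sound) yields a
  missing flag for that sound only.
- **Spectral bands** — RMS of the window PCG band-passed to 20–50 / 50–100 /
  100–240 Hz (S low / S mid / S high); S1 low is the 20–50 Hz RMS restricted
  to ±40 ms around S1 on the ensemble beat.  Band definitions are
  configurable defaults (the upper edge sits below the 250-Hz Nyquist of the
  500-Hz default rate).
- **QRS duration** — width of the contiguous region around R where the
  ensemble ECG magnitude exceeds 10% of the R amplitude.
- **Impedance pneumography** — respiration rate per channel as the dominant
  spectral peak in 0.07–1.0 Hz (zero-padded periodogram with parabolic
  interpolation; missing when no peak stands 3× above the in-band median);
  relative tidal volume as mean peak-to-trough respiratory excursion (after
  0.7-Hz low-pass isolating respiration from cardiac ripple) divided by the
  channel's mean impedance; mean impedance of channel 1.

Missing features are flagged, never silent NaN; the model matrix median-
imputes them with companion indicator columns.  An observation loses its
heart-sound block (6 of 16 signal features) when the PCG is dead, which is
tolerated; beyond 45% missing the observation is dropped.

## Models

Feature selection fits a seeded random forest (200 trees) per target on all
registry features and keeps those with impurity importance > 2% (importances
normalised to sum to one); demographics compete on equal terms.  The SBP and
DBP estimators are fixed seeded ensembles — random forest (100 trees),
gradient-boosted trees (100), and bagged decision trees (50), predictions
averaged — chosen for exact reproducibility over an automated,
time-budgeted model search; ensemble composition is configuration, not a
search result.  The demographics baseline uses the identical ensemble and
hyperparameters.  Models serialise losslessly (reload gives bit-identical
predictions).

## The synthetic study generator

The generator emulates the *structure* of a BP-validation study, not the
morphology of real pathology:

- **Cohort** — n subjects stratified over the four JNC-7 classes
  (default fractions 20/37/26/18%; printed percentages sum to 101%, so
  fractions within 2% of unity are accepted as-is).  Counts are the floor of
  each fraction with the residual assigned to the largest class.  Entry BP
  is drawn inside each class's cell; age ranges shift upward with class
  (hypertension prevalence rises with age); sex alternates through a seeded
  permutation; height/weight from sex-specific normals.
- **Protocol** — four condition blocks (static, warm stimulus + rest,
  cold pressor + walk, rest) with three readings after each activity and
  ≥ 60 s (default 75 s) between readings.  Condition offsets to (SBP, DBP):
  static (0, 0), warm (−9, −5), cold+walk (+12, +8), rest (−3, −2) mmHg,
  with subject-level reactivity SD (3, 2) and observation-level SD (4, 3)
  mmHg — magnitudes typical of thermal/exercise BP modulation.
- **Observers** — each reads true BP + N(0, 2 mmHg), rounded to the 2-mmHg
  grid (ties to even, since "nearest 2 mmHg" does not fix the tie rule);
  about 9% of pairs then disagree by > 4 mmHg, exercising the retake rule.
  The wrist-cuff column carries +3 mmHg bias and 7-mmHg noise so its MAD
  exceeds a competent model's.
- **Waveforms** — sum-of-Gaussians ECG beats (P, QRS, T; the QRS Gaussian's
  σ is qrs_duration/(2√(2 ln 10)) so the 10%-threshold width measurement
  recovers the planted duration exactly); Gaussian-windowed tone bursts for
  S1 (30 Hz, the low-frequency-dominant sound) and S2 (70 Hz); impedance as
  baseline + tidal sinusoid + 3% cardiac ripple; an activity channel whose
  injected movement epochs corrupt all channels.  Default rates: ECG/PCG
  500 Hz, impedance 50 Hz, activity 25 Hz.  True BP is piecewise constant
  between scheduled readings so the window preceding an observation carries
  exactly that observation's physiology.
- **Planted coupling** — R→S2 = 0.300 − 0.0012·(SBP − 120) s (clipped to
  [0.19, 0.40] s), S1/S2 RMS ratio = 1.5 + 0.02·(DBP − 80), and a weak
  tidal-volume link.  The direction matches systolic-time-interval
  physiology (higher pressure, earlier aortic closure relative to R); the
  magnitudes are *not* physiological constants — they are set so the planted
  effect is reliably detectable at the default study size (40 subjects,
  ~12 observations), which is the coupling's entire purpose: giving
  parameter-recovery and model-superiority tests a known answer.  With
  coupling disabled the generator is a null model in which signal features
  are independent of BP.

A feature-level fast path (`simulate_feature_dataset`) draws the feature
matrix directly from the planted truth (coupling + subject-level +
observation-level noise, observer-reconciled targets with protocol retakes),
bypassing waveform synthesis.  Monte-Carlo studies over many seeds (feature
selection, superiority, bootstrap behaviour) use this path; the waveform
path is exercised by the recovery and end-to-end tests.

### What passing tests do and do not show

The generator's waveforms are smooth closed forms: no baseline wander,
powerline interference, murmurs, ectopy or electrode artifacts beyond the
injected movement epochs, and the signal↔BP couplings are clean affine maps.
Green tests therefore demonstrate that the *pipeline machinery* is correct —
quality rules, window association, feature extractors recover planted
physiology to within a sample, the statistics match their definitions, the
comparison detects a planted effect and stays silent under the null.  They
say nothing about accuracy on real patients, which requires clinical data
this package does not ship.

## Numerical choices

- Half-open windows, 1-s mask granularity; window ties in centered mode go
  to the later window.
- Rounding to the 2-mmHg grid uses round-half-to-even.
- Zero-phase (forward-backward) Butterworth filtering throughout, order 4
  (order 2 for the R-peak band-pass).
- Percentile bootstrap CIs (2.5/97.5); p-values floored at 1/n_resamples;
  bootstrap index matrices drawn once per call from `numpy.random.default_rng(seed)`.
- Degenerate inputs: empty pair sets, zero-variance targets, all-NaN feature
  columns, sub-1-s recordings and protocol overruns raise typed errors;
  constant impedance yields rate = missing, tidal volume = 0.

## Problem sizes used by the test suite

Unit and property tests run on seconds-scale fixtures.  The Monte-Carlo
suites use 50 seeded runs at 40 subjects × 12 observations (feature-level
path, 2,000 bootstrap resamples — the verdict depends on the CI sign, which
is stable well below the 10,000 used in reported runs), 500 outer
replications for CI coverage, and two 8-subject waveform runs for the
determinism check.  `scripts/acceptance.py` runs the full 120-subject,
14-observation study with the complete 10,000-resample bootstrap.

## Known limitations

- The ensemble composition is a fixed specification; no model search or
  hyperparameter tuning is performed, so absolute accuracies are not tuned.
- Observation-level splitting shares subjects between train and test, as
  study descriptions of random observation splits imply; models can exploit
  subject identity.  The subject-level split mode quantifies that leakage
  but is not the default.
- The "centered" window mode never extends more than half a window past the
  observation.
- EDF export is not provided; recordings use the package's CSV + JSON
  header layout only.
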