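# Methods

`liftrisk` implements an automatic biomechanical-risk classification chain
for repetitive lifting, driven by a single sternum-mounted inertial
measurement unit (IMU), together with the Revised NIOSH Lifting Equation
(RNLE) that defines the risk labels. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
cohort does and does not establish.

## The lifting equation

The RNLE models the recommended weight limit of a lifting task as

    RWL = LC · HM · VM · DM · AM · FM · GM

with a load constant LC (25/20 kg for males under/over 45 years, 20/15 kg
for females) and six multipliers in [0, 1] penalising horizontal grip
distance H, vertical origin height V, vertical displacement D, asymmetry
angle A, lifting frequency/duration and coupling quality. The lifting
index LI = AWL/RWL (actual weight over the limit) classifies the task:
LI < 1 acceptable, LI ≥ 1 at risk (the boundary is classified
conservatively as risk). The continuous multipliers use the standard
published metric forms (HM = 25/H, VM = 1 − 0.003·|V − 75|,
DM = 0.82 + 4.5/D, AM = 1 − 0.0032·A, with the usual floors and
out-of-range zeroes); FM and GM are look-ups in the published frequency ×
duration × height and coupling × height tables, shipped as CSV data files
and stamped with a table version (`niosh-1994-metric`) in every result.
Frequencies between table rows resolve to the next higher row (the
conservative choice). D = 0 is treated as minimal displacement (DM = 1).
A task geometry extreme enough to zero a multiplier gives RWL = 0; the LI
is then undefined and the result carries an `infinite_risk` flag rather
than a number.

Published LI values for comparable task configurations vary with the
national adaptation of the multiplier tables; recomputing a typical
"acceptable" configuration (male < 45, 6.5 kg, H = 40 cm, 70→120 cm,
4/min, ≤1 h, good coupling) with these tables gives LI = 0.55, while
discretised table variants print values near 0.57. The package documents
the textbook value; classification is insensitive to the difference.

## Signal conditioning and lift segmentation

Recordings are 6-channel series (ax, ay, az in m/s²; vx, vy, vz in rad/s;
x vertical) with a mandatory sampling-rate field. The reference channel
(vertical acceleration by default) passes through:

1. **Band-pass** — 8th-order Butterworth, 1–50 Hz, applied zero-phase
   (forward–backward, SOS form) so detected boundaries are not
   phase-shifted. The upper cutoff is clamped to 0.45·fs when the
   sampling rate cannot support 50 Hz (e.g. fs = 20 Hz); the clamp is
   logged and recorded in the run manifest.
2. **Envelope** — rectification followed by a Savitzky–Golay filter,
   polynomial order 3. The default frame is 1001 samples; an `auto` mode
   sets the frame to the nearest odd number of samples to 0.4·fs·(lift
   period). At 128 Hz the fixed frame spans 7.8 s against a 15 s lift
   period and blurs burst edges (measured median boundary error 0.52 s vs
   0.15 s for `auto` on synthetic sessions); `auto` is therefore the
   recommended mode whenever boundary accuracy matters, and the mode used
   by the segmentation-recovery tests. Frames longer than the series are
   shrunk to the largest valid odd length (logged).
3. **Thresholding** — maximal runs with envelope ≥ θ, θ = α·P95(envelope),
   α = 0.3 by default; runs separated by < 1 s are merged, runs shorter
   than 1 s discarded. Two guards make the relative threshold sane: a
   flat-zero envelope yields no detections, and a *contrast guard*
   declares "no activity" when P95 < 2 × median — without it a featureless
   noise envelope would sit entirely above any relative threshold and
   produce one giant run. When the expected lift count is known (a
   metronome-paced protocol), α is tuned by bisection on [0.05, 0.95]
   until the count matches; failing that, the closest count is returned
   with a warning.

Sample intervals are 0-based half-open [start, end). ROIs are checked
sorted, disjoint and in bounds on every output.

## Feature catalogue

Per lift and channel, 11 time-domain and 8 frequency-domain features are
computed (19 × 6 = 114 columns). Conventions that needed a decision:

- **MEAN** is the mean of the rectified segment. A signed band-passed
  segment has mean ≈ 0; reference per-class statistics for this feature
  are positive while the 25th percentile is negative, which is only
  consistent with a rectified mean. SD and the percentiles stay on the
  signed segment.
- **HM** (harmonic mean) of a signed zero-crossing signal is numerically
  explosive (reciprocals near zero). Samples with |x| < 1e-12 are
  excluded and the instability is documented rather than patched: the
  feature behaves exactly as unstably as its field-reported statistics
  suggest, and it never survives screening.
- **ZC** counts changes of sign state (−, 0, +) between consecutive
  samples; **NSC** applies the same count to first differences.
- **FD** is Katz's waveform fractal dimension on the (sample index,
  value) path, bounded below by 1, with degenerate paths defined as 1.0.
  (A Higuchi variant was considered and not included: the reference
  statistics ~1.00–1.01 match Katz's bounded form.)
- The **power spectrum** is the raw one-sided FFT periodogram of the
  unwindowed segment, DC bin excluded, scaled so a unit sinusoid carries
  total power 1/2. **EN** is Shannon entropy of the normalised spectrum
  divided by log K (0 for one bin, 1 for uniform). **KU/SK** are moments
  of the distribution of spectrum *values* — this reading produces the
  large magnitudes (~10²) seen in practice for concentrated spectra; the
  alternative spectral-shape moments over frequency are available as
  `spectral_shape`. **MDF** is the smallest frequency at which cumulative
  power reaches 50%; ties and bin placement follow the cumulative-sum
  definition exactly (property-tested against a brute-force loop).

## Screening

Features are compared between the two trials of each subject with lift-i
paired to lift-i (260 pairs in the full design; per-subject-mean pairing
is available). Shapiro–Wilk at the 95% level on each class gates a
two-tailed paired t-test against the Wilcoxon signed-rank fallback
(normality of the paired differences is available behind a flag). No
multiple-testing correction is applied by default, matching common
practice for descriptive per-feature tables; Benjamini–Hochberg is
available. Identical classes short-circuit to p = 1. Fewer than 8 pairs
is an error.

## The classifier chain

1. **Correlation pruning**: greedy scan in catalogue order; of any pair
   with |Pearson r| > 0.7 the later feature is dropped; constant columns
   are dropped with a warning. Deterministic.
2. **Outlier removal** (single pass): a preliminary logistic fit supplies
   Cook's distances and hat-matrix leverages. Rows with Cook's D > 1
   (Cook–Weisberg rule) or leverage > 3(k+1)/n are removed. Milder
   textbook cutoffs (D > 4/n, 2× mean leverage) were measured to discard
   ~8–14% of perfectly clean Gaussian data — the 2×-mean rule alone flags
   the ~8% χ² leverage tail — which is not outlier removal but data loss;
   the stricter defaults operate at the few-instances scale a practitioner
   would expect, and both cutoffs are configurable. Note that logistic
   influence is inherently blind to extreme points on the *correct* side
   of the boundary (their IRLS weights vanish); only wrong-side or
   high-leverage points can be flagged.
3. **Logistic regression** with iterative refinement: maximum-likelihood
   fit, then drop predictors with Wald p > 0.05 or per-unit odds ratio
   within 0.01 of 1, refit, until stable (≤ 10 rounds, all rounds
   recorded). Predictors are standardised internally (L-BFGS warm start,
   Newton polish) because raw feature scales spanning five orders of
   magnitude stall the unstandardised MLE; coefficients and odds ratios
   are reported back-transformed to original units, and p-values are
   invariant under the reparametrisation. Perfect separation is flagged
   and reported from a weakly L2-regularised fit; p-based pruning is
   suspended in that case.
4. **Evaluation**: resubstitution (apparent) confusion matrix with actual
   classes as rows (NO_RISK first), accuracy, sensitivity (= NO_RISK
   recall) and specificity (= RISK recall) as percentages rounded
   half-up to one decimal. The events-per-variable ratio (smallest class
   size / number of final predictors) is reported and should exceed 10.
   The report labels the protocol "apparent (resubstitution)"; no
   train/test split is performed on the replication path.

## Synthetic cohort

The generator emulates the study design: 13 subjects × 2 trials
(NO_RISK, RISK) × 20 rhythmic lifts at 4/min over 5 min. Each lift is a
Hann-windowed sinusoidal burst (1–4 Hz, 3–5 s, ±0.25 s timing jitter)
on Gaussian noise (σ = 0.05), at 128 Hz by default (20 Hz supported).
Class structure is multiplicative: RISK bursts scale by γ^e_c per
channel, with exponents e_c ∈ [0.5, 1.1] strongest on the z axes and
weakest on vertical acceleration, and burst frequencies scale by γ^0.6 —
the direction and relative size of the published per-channel and
spectral effects. Amplitude variability uses lognormal factors: per
subject (σ = 0.20), per lift shared across channels (σ = 0.10) and per
channel (σ = 0.10), chosen so within-class coefficients of variation of
amplitude features land near the published ~0.27–0.35. At γ = 1 every
class effect vanishes exactly, so the null pipeline is honest. All
randomness flows from one `SeedSequence`; identical seeds give
bit-identical cohorts.

At γ = 1.3 the full chain reaches ~75–90% resubstitution accuracy
across seeds (mean ≈ 80%, the regime of the reference results); the
default γ = 1.2 sits lower. What passing synthetic tests show: the
segmentation, features, screening and model code recover a known
multiplicative class structure at realistic noise levels. What they do
not show: performance on real lifting kinematics — the generator has no
biomechanical forward model, no fatigue or posture drift, no metronome
phase structure beyond Gaussian jitter, and its class effect is purely
multiplicative in amplitude and frequency.

## Problem sizes and runtime

The default test suite runs the segmentation-recovery check on 50 full
sessions, the screening calibration on 200 null replicates plus 100
power replicates, and the end-to-end check on 20 full 520-instance
cohorts at γ = 1.3 plus 3 null cohorts — about 4 minutes in total on one
CPU. The acceptance script runs one full cohort (~30 s). The
distribution-fidelity (Kolmogorov–Smirnov) check of the generator runs
on 3 seeds of a reduced cohort in the unit suite; the property is
seed-uniform, so the reduction does not change what is being checked.

## Known limitations

- The RNLE tables are the standard metric variant; national adaptations
  print slightly different LIs for the same geometry.
- The envelope threshold policy (α·P95, merge/min-duration, contrast
  guard, count-matched bisection) is engineering around an "empirical
  threshold"; on signals with strongly non-stationary baselines the
  relative threshold may need per-recording α tuning.
- Odds-ratio pruning operates on per-original-unit odds ratios and is
  therefore scale-sensitive by construction (a deliberate mirror of
  common statistical-package reporting); rescaling a feature changes
  whether the |OR − 1| ≤ 0.01 rule fires, while Wald-p pruning is
  scale-invariant.
- Resubstitution metrics are optimistic; the subject-wise split needed
  for honest generalisation estimates is out of the replication path.
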