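# liftrisk

Biomechanical risk classification for repetitive lifting tasks from a
single sternum-mounted inertial measurement unit (IMU).

Work-related musculoskeletal disorders are strongly associated with manual
lifting. The accepted assessment tool, the Revised NIOSH Lifting Equation
(RNLE), scores a lifting task by its geometry and rhythm:

    RWL = LC · HM · VM · DM · AM · FM · GM        LI = AWL / RWL

where RWL is the recommended weight limit, LC a sex/age load constant and
the six multipliers penalise horizontal distance, vertical origin,
displacement, asymmetry, frequency/duration and coupling quality. A
lifting index LI < 1 is acceptable; LI ≥ 1 flags potential risk. Scoring
tasks this way requires an ergonomist at the workplace — `liftrisk`
implements the automatic alternative: classify the RNLE risk class
directly from the inertial signature of the lifts, recorded by one
chest-worn IMU.

The package provides, as importable modules and a CLI:

- **rnle** — RWL / LI / risk class from a task description, with the
  standard multiplier formulas and FM/GM look-up tables as data files;
- **signal** — zero-phase Butterworth band-pass (1–50 Hz, Nyquist-aware),
  rectified Savitzky–Golay envelope, and automatic per-lift segmentation
  by envelope thresholding (optionally count-matched to a known protocol);
- **features** — 19 time/frequency features (signal area, peak-to-peak,
  percentiles, zero crossings, curve length, Katz fractal dimension,
  spectral entropy, median/mean frequency, …) per channel: a 114-column
  table per cohort;
- **screen** — paired per-feature statistics (Shapiro–Wilk-gated paired
  t / Wilcoxon) between the risk classes;
- **model** — Pearson-correlation pruning (|r| > 0.7), Cook's-distance /
  leverage outlier removal, and a binary logistic regression iteratively
  pruned by Wald p-values and odds ratios, evaluated by confusion matrix,
  accuracy, sensitivity and specificity;
- **synth** — a seeded generator of 6-channel lifting sessions with
  ground-truth lift windows (13 subjects × 2 trials × 20 lifts at 4/min
  by default), whose class effect reproduces the direction of real
  load effects (larger amplitude and power, higher spectral content);
- **io / pipeline / cli** — plain CSV+JSON formats, a run manifest, and
  the end-to-end `run` command.

## Worked example

Score a lifting task:

```
$ liftrisk rnle --sex male --age under45 --load 6.5 --h 40 --v0 70 \
                --v1 120 --freq 4 --duration short --coupling good
{
  "lc_kg": 25.0,
  "hm": 0.625, "vm": 0.985, "dm": 0.91, "am": 1.0, "fm": 0.84, "gm": 1.0,
  "rwl_kg": 11.764593749999998,
  "li": 0.5525052660658173,
  "risk_class": "NO_RISK",
  ...
}
```

A 6.5 kg load lifted from 70 to 120 cm at 4 lifts/min is under half the
recommended limit (11.76 kg): LI ≈ 0.55, no risk. The same geometry with
12.5 kg from 20 cm gives LI ≈ 1.32: at risk.

Run the whole chain on a synthetic cohort:

```
$ liftrisk run --seed 1 -o out/
520 instances; accuracy 71.3% (sens 72.4%, spec 70.2%); artifacts in out/
```

(The default configuration uses the generator's default class gain of
1.2; the 1.3 operating regime used by the acceptance script classifies
more accurately, ~75–90% depending on seed.)

`out/` then contains the per-lift windows (`rois.csv`), the 114-column
feature table (`features.csv`), the per-feature screening table
(`screen.csv`), the model report with coefficients, odds ratios, removed
outliers and confusion matrix (`report.json`), and the run manifest with
the full configuration, seeds and any warnings (`manifest.json`).

In library form:

```python
from liftrisk import PipelineConfig, SynthConfig, SegmentConfig, run_pipeline

config = PipelineConfig(seed=1, synth=SynthConfig(class_gain=1.3),
                        segment=SegmentConfig(sg_frame_mode="auto"))
result = run_pipeline(config)
print(result.model_report.metrics.accuracy)
```

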