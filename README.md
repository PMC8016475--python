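# pupilstyle

Pupillometry-based analysis of perceptual style: from raw 500 Hz
eye-tracker samples of a bistable rotating-cylinder experiment to
per-participant indices and trait-correlation statistics, with a
synthetic-cohort simulator so the entire pipeline runs and validates
without any external data.

## The science

When observers view a transparent structure-from-motion cylinder whose two
surfaces are black and white dots, the pupil tracks the luminance of the
*attended* surface: it dilates when the black dots are perceived in front
and constricts when the white dots are. The sustained pupil-size
difference between black-front and white-front periods is therefore an
objective index of whether attention is focused locally on the foreground
or spread globally — a perceptual-style measure that requires no button
presses. Across a cohort, the amplitude of this modulation covaries with
autistic-like personality traits measured by the Autism-Spectrum Quotient
(AQ, 0–50).

The package implements:

- **`synth`** — a generative cohort model: stochastic stereo-depth swap
  schedules (90% uniform with mean 5 s / SD 2 s, 10% long-range outliers),
  1.2 s linear disparity ramps, sinusoidal dot kinematics peaking at
  3.9 deg/s, and raw recordings containing a sustained color-locked pupil
  modulation (amplitude correlated with AQ), switch-locked constrictions,
  keypress-locked dilations, blinks, OKN-like gaze and report behavior.
- **`preprocess`** — artifact rejection (trial-median band, 0.2 mm floor,
  2.5 mm/s speed rule with ±10 ms purge), per-trial linear detrending,
  gaze recoding/smoothing/differentiation with a 3.9 deg/s cap, and median
  downsampling of all channels to a common 10 Hz grid (empty bins → NaN).
- **`epochs`** — 10 s event-locked segments (swap- or switch-aligned),
  30% missing-data exclusion, 200 ms pre-event baseline, per-label median
  traces, and the scalar indices: pupil-size difference, mean pupil
  response, gaze-velocity difference, report accuracy/latency via peak
  cross-correlation, mixed-percept rate, and odd/even split-half variants.
- **`stats`** — Pearson r with 95% CI and p, the two-sided JZS Bayes
  factor for correlations (reported as lgBF = log10 BF10, computed by
  numerical integration), the JZS two-sample Bayes factor, partial
  correlations, Fisher z comparison of correlations, Spearman-Brown
  prophecy and disattenuation, and a combined reliability suite.
- **`io` / `cli`** — TSV sample logs and event files, a flat YAML run
  configuration holding every design constant, and a
  `simulate → preprocess → analyze → report` command-line pipeline.

## Worked example

```python
from pupilstyle.pipeline import run_synthetic_cohort
from pupilstyle.stats import pearson_with_evidence

tab = run_synthetic_cohort(seed=7)          # 53 participants, 30 trials each
print(pearson_with_evidence(tab.aq, tab.pupil_diff))
```

```
r = 0.45 [0.20, 0.64], p = 0.000839, lgBF = 1.44 (n = 53)
```

The cohort was generated with a planted AQ–amplitude correlation of 0.45;
the full pipeline (artifact rejection → detrend → 10 Hz → epochs →
indices) recovers it: r is the Pearson correlation between each
participant's AQ score and their pupil-size difference (mm, black-front
minus white-front over the 2 s after a depth swap), the bracket is the
Fisher-z 95% CI, and lgBF > 0.5 is substantial evidence for a correlation.

The same pipeline from a shell:

```
pupilstyle simulate   --out run/ --seed 7
pupilstyle preprocess --out run/
pupilstyle analyze    --out run/
pupilstyle report     --out run/        # prints the index-vs-AQ grid
```

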