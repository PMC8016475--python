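# Methods

## The measurement problem

`pupilstyle` analyzes pupillometry from a bistable structure-from-motion
experiment. Observers view a dot cylinder whose two transparent surfaces —
one black, one white — move in opposite directions; binocular disparity
places one color in front, and the depth assignment swaps stochastically.
Because the pupil responds to the luminance of the *attended* surface, the
sustained pupil-size difference between black-front and white-front periods
indexes how strongly an observer focuses the foreground: an objective,
report-free correlate of local vs global perceptual style. The pipeline
estimates this index per participant and relates it to Autism-Spectrum
Quotient (AQ) scores across the cohort.

## Signal model

Each participant yields 30 trials of 60 s monocular recordings at 500 Hz:
pupil diameter (mm) and horizontal/vertical gaze (deg). The synthetic
observer generates the pupil trace as a sum of components that the analysis
is designed to separate:

```
pupil(t) = baseline + drift·t/T
         + a_sus · K_tau * s(t − d)        sustained, color-locked
         − a_con · G(t − t_flip − l_con)   transient, switch-locked constriction
         + a_dil · G(t − t_key − l_dil)    transient, keypress-locked dilation
         + eta(t)                          correlated measurement noise
```

where `s(t) = +1` when the black dots are perceived in front and `−1`
otherwise, `K_tau` is a first-order low-pass (time constant `tau`),
`G` is a gamma-like bump, and blinks zero the pupil channel. Gaze shows
antagonistic optokinetic nystagmus (OKN): slow phases at `okn_gain` times
the mean foreground surface velocity `(2/pi)·v_peak`, with fast resets that
the analysis removes via its speed cap.

Key generator parameters (units, default, rationale):

- `sustained_amp` (mm, cohort mean 0.03, SD 0.04): the trait-linked
  component; across the cohort `amp_i = mean + scale·(rho·z_i +
  sqrt(1−rho²)·eta_i)` with `z_i` the standardized AQ draw, so
  corr(AQ, amp) = `rho` (default 0.45) in expectation.
- `sustained_tau` (s, 0.8): the data only constrain the modulation to be
  sustained over seconds; a sub-second first-order response is the simplest
  shape with that property.
- `sustained_latency` (s, 0.6): pupil responses trail their trigger by
  roughly 0.5–1 s. The default places the drive flip at the end of the
  1.2 s disparity ramp (the epoching reference), which also makes the
  noiseless step model exact: post-swap level `+a` against pre-swap
  baseline `−a` gives an index of `4a` with an instantaneous kernel.
- `noise_sd` (mm, 0.05) with `noise_smooth_s` (s, 0.1): measurement noise
  is Gaussian-correlated, not white — a 500 Hz white process would exceed
  the 2.5 mm/s physiological speed threshold at essentially every sample,
  which no real trace does. The noise is synthesized on a coarse grid and
  linearly upsampled (band-limited by construction).
- swap schedule: 90% of inter-swap intervals uniform with mean 5 s and
  SD 2 s (support `5 ± 2·sqrt(3)` s, the unique uniform with those
  moments), 10% uniform on [1.2, 60] s. The nominal 0.5 s lower bound of
  the outlier range is clipped at the ramp duration so consecutive ramps
  never overlap.
- reports: keypress latency truncated-normal (mean 1.0 s, SD 0.3 s, floor
  0.2 s); each switch passes through a mixed-percept episode whose
  deterministic duration makes mixed time exactly the configured fraction
  of trial time (default 2.86%).
- OKN gain: 85% of observers track the front surface (positive gain,
  magnitude ~N(0.8, 0.15)), 15% the rear (negative), independent of AQ.

## Preprocessing

Pupil, per trial: (1) remove samples >1.5 mm from the trial median
(median over all finite samples, computed before the floor rule) or
<0.2 mm; (2) remove the ±10 ms epoch around any adjacent retained pair
whose implied speed exceeds 2.5 mm/s, using the pair's actual time
separation so gaps cannot create spurious spikes; (3) subtract the OLS
line fit on valid samples. Gaze: negate when the black dots moved
leftward (so positive = toward the black dots), 20 ms box-car smoothing
(truncated at edges and gaps), first difference × 500 Hz, and removal of
speeds above 3.9 deg/s (the stimulus peak), which strips saccadic fast
phases. All four channels — pupil, slow-gaze velocity, stereo-depth state
and report state — are then median-downsampled into non-overlapping,
half-open, left-edge-timestamped 100 ms bins; an empty bin is NaN. The
median of an even count is the midpoint of the central pair.

## Epochs and indices

Traces are parsed into 10 s segments (100 bins, [−5, +5) s) centered on
either a stereo-depth swap (reference: ramp end) or a perceptual switch
(reference: the CW↔CCW keypress), labeled by the post-event foreground
color (stereo-defined or reported respectively). Segments with more than
30% missing pupil data are excluded (strict inequality). Pupil segments
are baseline-corrected by the median of the 200 ms (two bins) before the
event; if both bins are missing the nearest preceding valid bin is used
(configurable to exclusion instead). Per label, traces are aggregated by
the bin-wise median across segments; scalar indices:

- `pupil_diff` / `gaze_vel_diff`: mean of (black-front − white-front) over
  [0, 2] s after a swap, or [−1, +1] s around a switch (the switch leads
  its causes by the ~1 s report latency);
- `mean_response`: the two traces averaged together over [1, 2] s (swap)
  or [0, 1] s (switch) — overall event-locked pupil response;
- `accuracy`/`latency`: peak and arg-peak of the normalized
  cross-correlation between the concatenated report and stereo-depth
  state channels (interior NaNs linearly interpolated), scanned on the
  10 Hz lag grid over [0, 5] s, ties broken toward the smallest lag;
- `mixed_pct`: percent of reporting time (first keypress to trial end) in
  the mixed state.

Split-half estimates rerun the entire index pipeline on odd- and
even-numbered trials (1-based acquisition order).

## Inference

Correlations are Pearson; p-values from the t transform (n−2 df), 95% CIs
via Fisher z. Evidence is the base-10 log of the two-sided JZS Bayes
factor for a correlation,

    BF10 = sqrt(n/2)/Γ(1/2) ∫ (1+g)^((n−2)/2) [1+(1−r²)g]^(−(n−1)/2)
                               g^(−3/2) e^(−n/(2g)) dg,

evaluated by adaptive quadrature on a peak-normalized log-integrand (the
result is stable to grid refinement at <1e-3). The two-sample Bayes factor
integrates the noncentral-t likelihood against a Cauchy(0, √2/2) effect
prior. Partial correlations use the first-order residual formula (p with
n−3 df); two independent correlations are compared by the Fisher z
statistic. Reliability: split-half r pools both experiments' (odd, even)
pairs, Spearman-Brown boosts half-length estimates
(`r_full = 2r/(1+r)`), and the test-retest correlation between the main
and no-report experiments is disattenuated by
`r / sqrt(rel_main · rel_retest)`; corrected values outside [−1, 1] are
flagged, never clipped.

## Numerical conventions and degenerate inputs

Missing data are NaN end-to-end. A trial with fewer than 2 valid samples
is unusable; an epoch with no valid pre-event bin is dropped; a label with
no epochs leaves that participant's index undefined; a constant report
channel makes accuracy undefined and excludes the participant from
accuracy analyses. Epoch bin edges are aligned by rounding the event time
to the nearest bin boundary. All randomness flows from a single cohort
seed through per-participant `SeedSequence` spawns, so outputs are
byte-identical across reruns.

## Validation problem sizes

The distribution checks use 10,000 sampled intervals; oracle-equivalence
checks use 1,000 random traces (downsampling) and dozens of random draws
(cross-correlation, partial correlation). Trait-recovery runs the full
pipeline on 53-participant, 30-trial cohorts across 20 seeds per
condition, matching the study's cohort geometry.

## What the generator does and does not emulate

It reproduces the stimulus timeline statistics, the three pupil components
with their sign structure, OKN-like gaze with fast phases, blinks as
signal dropouts, report latency/mixed-percept behavior, and a planted
AQ-amplitude correlation. It does not model pupil light/near reflex
dynamics beyond the first-order kernel, item-level AQ responses, vergence,
microsaccades, torsional or vertical nystagmus, or drift/noise
nonstationarities of real recordings. Passing tests therefore establish
that the *pipeline* is correct and unbiased under the assumed signal
model — not that the physiological model itself is complete.

## Known limitations

The switch-aligned and swap-aligned indices are not interchangeable (their
windows and references differ by design); the sustained-component kernel
and transient shapes are conventions, constrained only in sign and
timescale; the correlation Bayes factor matches the printed evidence
values under the JZS prior family, and other defensible prior widths shift
lgBF by a few hundredths.
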