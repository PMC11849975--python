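# Methods

## The measurement chain

The weight-drop rig delivers a blast-like overpressure to larvae inside a
closed, media-filled syringe: a calibration weight falls down a guide tube
onto the plunger, and an automotive fuel-line pressure transducer read by a
10-bit Arduino ADC records the pressure time course for a nominal 1 s after
a photoresistor trigger. Counts convert to pressure through a fixed affine
chain

    voltage = 5 · output / 1023
    PSI     = (voltage − 0.5) · 37.5
    kPa     = PSI · 6.895

applied exactly, with no rounding. One ADC step is 1.264 kPa — the
resolution floor for any peak read from a quantized trace. Counts below the
102.3-count sensor offset imply negative pressure; they are retained and
flagged rather than clipped, because the trailing baseline estimate needs
the unmodified signal and rail artifacts should stay visible.

The transducer is calibrated statically: a mass resting on the plunger must
read `weight / barrel cross-sectional area` (Pascal's principle, g =
9.80665 m/s² exactly). `expected_static_pressure` and `calibration_error`
implement that check; no dynamic (frequency-response) correction is
attempted or claimed.

## Wave segmentation and dose metrics

A pressure wave is the excursion from the first sample above baseline until
the first sample back at baseline. In noisy data the literal rule needs two
numerical supports, both exposed as parameters:

- **Baseline** is estimated from data, not assumed zero, because the 0.5 V
  sensor offset can drift: mean and SD (ddof=1) over a quiescent window,
  by default the trailing 100 ms of the trace (ringing has decayed by
  then), switchable to a leading window for long pre-trigger captures. At
  least 10 samples are required.
- **Exceedance**: a wave opens strictly above `baseline + exceedance` and
  closes at the first sample at or below that level (same level both ways,
  matching the stated rule; no hysteresis gap). Default exceedance is
  `max(3·noise_sd, 1 kPa)`. Waves shorter than `min_duration` (default
  1 ms, settable to 0 for the literal rule) are discarded as single-sample
  blips. A wave still open at the end of the trace is closed at the last
  sample and keeps it.

Per-wave peak and mean are computed over the above-threshold samples as a
uniform-sample mean (identical to a time average at uniform sampling). The
**maximal pressure** — the dose metric every downstream model uses — is the
global trace maximum and is deliberately independent of segmentation
parameters. Inter-wave intervals are reported start-to-start, with the
end-to-start convention also available, since the field's "time between
waves" phrasing does not pin the reference points. Replicate drops of one
configuration are summarized as mean ± SEM (SD/√n, ddof=1) of maxima and
their relative standard deviation, RSD = 100·SD/mean, the rig's
consistency metric.

Gravitational potential energy `m·g·h` and the ratio between two drop
configurations separate settings that peak pressure alone conflates: 200 g
from 27 cm delivers a similar maximal pressure to 100 g from 108 cm at half
the input energy.

## Behavioral phenotypes

Activity is the tracking export's distance moved per bin (bin width taken
from the file; the generators default to 1 s bins, 30 min recordings).
From it:

- **High-activity (seizure-candidate) bouts**: maximal runs of bins
  strictly above 64% of the highest single-bin activity in the pooled
  uninjured control group of the session. An all-zero control group gives
  threshold 0 and a warning. The threshold applies to per-bin activity —
  the export's native quantity.
- **Inactivity**: maximal runs of bins with activity ≤ ε (default ε = 0,
  strict zero) lasting ≥ 60 s, inclusive at the boundary ("1 min or
  more"); shorter pauses are ordinary quiescence. Total inactive time is
  the sum of qualifying bout durations.
- **Candidate-dead**: zero total activity over the recording. The flag is
  advisory only — floating and heartbeat cannot be read from the activity
  table — so exclusion always requires an explicit confirmation and is
  logged, never silent.
- Manual seizure stages (none / stage I / stage II–III) and fin-poke
  stimulus responses on the 5-min grid are ingested as data; automated
  staging from kinematics is out of scope by design.

## Dose-response models

Continuous responses regress on dose by ordinary least squares
(`fit_linear`: slope, intercept, R², two-sided slope p). Binary phenotypes
use maximum-likelihood logistic regression (`fit_logistic`) with covariates
on their natural scales — kPa and drop count, unstandardized — so
coefficients exponentiate directly to per-unit odds ratios. Confidence
intervals are Wald on the log-odds scale, exp(β ± 1.96·SE). Because
per-kPa odds ratios sit near 1, `scale_odds_ratio` re-expresses them per k
units as ORᵏ and a percent change 100·(ORᵏ−1), rounded to one decimal in
reports only (OR 1.005/kPa → +64.7% per 100 kPa; OR 1.099/drop → +9.9%).

Complete separation is screened before fitting (per-covariate class-range
overlap) and after (non-finite SEs or |β| > 50); a `SeparationError` names
the covariate rather than silently fitting a penalized model. Model
discrimination is the ROC area in its Mann-Whitney form — the probability a
random positive outscores a random negative, ties counted ½ — computed on
fitted probabilities; an all-tied score vector returns 0.5.

Group comparisons against the shared uninjured control use one-way ANOVA
followed by Dunnett's two-sided comparisons under the equicorrelated
multivariate-t reference with pooled variance (scipy's implementation,
seeded for reproducible p-values). All-identical input returns adjusted
p = 1 for every group. Control reuse across comparisons is surfaced in
pipeline findings because it couples the tests that share it.

## What the generators emulate — and what they do not

`simulate_drop_trace` builds a bouncing-weight impulse train: impact speed
v₀ = √(2gh); restitution coefficient e gives impact k speed v₀·eᵏ and
flight time 2·v₀·eᵏ⁺¹/g between impacts; the train stops when a pulse falls
below `min_pulse_fraction` of the first. Pulse amplitude is proportional to
impact speed (`pressure_per_velocity`, default 60 kPa per m/s; holder and
syringe effects enter as multipliers on it). That proportionality is a
modelling convenience, not a constitutive law — it reproduces the
qualitative monotone trends (heavier and higher → larger pressure, ×4
height → ×2 amplitude) and makes no claim to the absolute kPa of any
physical device. Pulses are half-sine (or exponential-decay) with peaks
snapped to the 0.2 ms sample grid, pushed back through the calibration
chain, noised, and quantized to integer counts, so a noise-free round trip
recovers the pulse count exactly and each peak within one ADC step. The
nominal 1 s capture auto-extends when a slow bounce train outlasts it, plus
a 200 ms quiescent tail for baseline estimation. Default pulse width 5 ms
and the restitution/flight geometry put inter-wave intervals in the
tens-of-milliseconds regime seen on the rig.

`simulate_activity` reproduces the assay's biphasic dose structure:
truncated-normal baseline activity (mean 2.0, SD 0.5 units/bin), seizure
bouts (gain 5×) with probability peaking inside the 90–300 kPa
detectability band (Gaussian bump, peak probability 0.7), minute-scale
inactivity runs with probability logistic in dose (β₀ = −4, β₁ = 0.006/kPa
→ ~2% at dose 0, ~88% at 1000 kPa), and a suppression multiplier on
baseline activity that is exactly 1 at dose 0 and falls toward 0 past the
band. `simulate_phenotypes` draws Bernoulli outcomes from a stated logistic
model in pressure and drop count, the generative inverse of the fitted
models; default dose grid spans 33–1105 kPa, the range over which the
assay's phenotypes are reported.

The generators share none of the analysis code paths beyond the calibration
inverse, and every draw comes from one `numpy` Generator seeded from the
config — runs are bit-reproducible. They do **not** emulate: transducer
dynamic response or ringing, syringe/holder mechanics, tracking artifacts
(reflections, well-edge occlusion), between-plate variation, larval
mortality dynamics, or any absolute pressure calibration. Passing
round-trip tests therefore demonstrates the pipeline's internal
consistency under the assumed data structure, not agreement with any
measured animal dataset.

## Numerical choices and degenerate inputs

- Sample SD everywhere uses the n−1 denominator; SEM = SD/√n.
- ADC bounds are validated on read with the offending row named; times
  must be strictly increasing.
- `roc_auc` requires both classes; all-equal scores short-circuit to 0.5.
- `fit_logistic` requires ≥ 10 observations per covariate and both
  outcome classes.
- Dunnett p-values are capped at 1; a zero-pooled-variance input returns
  the "no difference" path rather than NaN.
- Percent changes are rounded to one decimal at the reporting boundary;
  full precision is kept internally.
- Problem sizes used by the test suite and acceptance script (hundreds of
  randomized oracle fixtures, 200 coverage simulations at n = 500,
  1000–2000 Dunnett null replicates) were chosen as the smallest sizes at
  which the statistical checks are stable across seeds.

## Known limitations

- Dosimetry is group-level: larvae within a syringe share the replicate
  mean maximal pressure; individual exposure is unobservable.
- The 64% threshold and inactivity ε are conventions over an export whose
  bin width and units vary by tracking configuration; cross-study
  comparability requires matching those settings.
- The Wald CI is first-order; near-separation data can make it optimistic
  (the separation screens catch only the complete case).
- The simulators are structural stand-ins, not physical models; no output
  of this package should be read as a prediction of absolute pressure for
  a real device configuration.
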