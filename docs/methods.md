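# Methods

This note documents the models, conventions and numerical choices behind
`mozkin`, and what its synthetic data can and cannot tell you about real
wind-tunnel recordings.

## Coordinate convention and configuration

All analysis constants live in `ArenaConfig`: a 200 × 60 × 60 cm arena
filmed at 60 frames/s over the 120 cm at the upwind end, a 6 cm exclusion
zone at the upwind screen ("bouncing"), a 6 cm any-wall plus 20 cm screen
mask for saccade analysis, a 30-frame minimum segment length, a 6-frame
(0.1 s) moving average, a 2000 deg/s saccade threshold, a 60-frame
post-saccade window, a 14 cm volume-of-interest (VOI) cylinder and a 300 s
response window.

The coordinate frame is: `x` along the wind axis increasing toward the
upwind screen (screen at x = 200 cm), `y` vertical, `z` lateral.  Tracking
systems do not agree on axis assignment, so this is a convention, stated
here and in the `io_config` module docstring; the planar ("vertical plane")
angular velocity uses the x–y components under it.

## Preprocessing

Frames are split into contiguous runs at frame-index gaps (tracking
dropouts), then masked:

* **standard profile** — drop frames with screen distance `200 − x < 6` cm;
  no length filter, no smoothing.  These frames feed flight duration,
  bouncing and VOI occupancy.
* **saccade profile** — drop frames closer than 6 cm to any of the six
  arena faces or 20 cm to the screen, drop surviving runs shorter than 30
  frames, then smooth x/y/z with the 6-frame moving average.

The even smoothing window is centred with the stencil i−3 … i+2 (a
half-frame asymmetry is unavoidable with an even window; on a locally
linear path the output is the input shifted half a step along the line).
Edge frames use the truncated window.  Segments shorter than the window are
passed through unchanged with a warning.

## Kinematics

Velocity at frame i is the central difference `(p[i+1] − p[i−1]) · fps/2`;
the unsigned angular velocity at i is the angle between the velocity
vectors at i and i+1 in degrees times the frame rate.  First/last frames
and zero-velocity frames are NaN and flagged, never silently zero.
Tortuosity of a window is summed 3-D step length over the endpoint chord
(≥ 1; NaN when the chord is shorter than 1e-9 cm).  Turn consistency is the
mean tortuosity over the 60 frames after each saccade centre; windows
truncated by the segment end are kept if at least 2 frames remain.

A saccade is a maximal run of frames whose angular velocity strictly
exceeds 2000 deg/s; its centre is the within-bout maximum (earliest frame
on ties).  Two choices deserve emphasis:

* **Variant** — thresholding uses the 3-D angular velocity by default
  (`saccade_angvel_variant = "xy"` selects the planar variant).
* **Smoothing and detection** — by default the detector runs on angular
  velocity computed from *unsmoothed* positions, while tortuosity and turn
  consistency use the smoothed path (`detect_on_smoothed` flips this).
  The reason is quantitative: at 60 fps the 6-frame moving average
  attenuates a realistic saccade (peak 3000 deg/s, ~5 frames wide, ~100°
  total turn) to a measured peak of roughly 1200 deg/s, below the 2000
  deg/s criterion — on smoothed positions the detector would be nearly
  blind.  Trajectory-reconstruction software computes angular velocity
  from its own unsmoothed fit, which is the behaviour reproduced here.

## Per-trial flight variables

A trial is a *responder* if any frame inside the filmed volume
(x ≥ 80 cm) occurs at t ≤ 300 s from release.  Non-responders carry no
flight variables.  For responders:

* `flight_duration_s` — filmed-volume frames outside the bouncing zone,
  divided by the frame rate;
* `prop_bouncing` — bouncing frames over all filmed-volume frames;
* `prop_voi` — frames with radial distance < 7 cm from the central wind
  axis, over standard-profile filmed frames;
* `saccade_freq_hz` — detected saccades per second of saccade-profile
  segment time;
* `turn_consistency` — mean post-saccade tortuosity across all events
  (NaN if no event yields a valid window).

Denominator conventions the source description leaves open are fixed as:
"total number of frames" means frames inside the filmed volume (the filmed
data); the VOI cylinder spans the filmed volume axially; the bouncing
predicate equals the standard mask predicate, so duration and bouncing
partition filmed time exactly.  VOI occupancy uses raw (unsmoothed)
positions.

## Group statistics

* **Response rates** — binomial (logit) GLM; omnibus likelihood-ratio χ²
  per factor (computed in closed form for a single factor, where the
  cell-means model is saturated — this also keeps the statistic finite
  under complete separation, which is flagged); pairwise contrasts of cell
  proportions on the proportion scale, Tukey-adjusted via the
  studentized-range distribution on |z|·√2.
* **Flight metrics** — Kruskal–Wallis with the standard tie correction
  (H = 0, p = 1 with a `ties` flag when every value is identical); Dunn's
  pairwise z statistics with the same tie correction,
  Benjamini–Hochberg-adjusted.  Groups with fewer than two values are
  excluded with a warning; missing values are dropped listwise per test.
* **PCA** — the five variables are z-scored (ddof = 1) and decomposed by
  SVD (equivalently, the correlation-structure eigendecomposition).  Rows
  with any missing variable are dropped and counted.  Sign convention:
  the largest-magnitude loading in each component is positive.
* **SSR mixed model** — `rate ~ genotype + log10_dose` (interaction
  optional) with a random intercept per sensillum, fit by REML
  (statsmodels MixedLM).  Fixed terms are tested with Wald F statistics
  using a **containment** denominator-df convention: a term constant
  within sensilla (genotype) is tested against `n_sensilla − rank` of the
  between-sensillum design; within-sensillum terms (dose) against
  `n_obs − n_sensilla − p_within`.  Pairwise genotype contrasts use the
  between df with the Tukey adjustment.  A near-zero random-intercept
  variance or an all-constant response is flagged `singular`.

Calibration, measured by simulation (1000 replicates, α = 0.05): the LR
omnibus rejects at ~0.047 with groups of 100 (it is mildly anticonservative,
~0.06, at groups of 30 — a known small-sample property of the χ²
reference); Kruskal–Wallis at ~0.051; the genotype F test at ~0.055 under
its own data-generating null (Gaussian sensillum intercepts visible in the
rate).

## Spike-rate statistic

For one presentation, the rate is (spikes in the 0.5 s stimulation window −
spikes in the preceding 0.5 s) × 2, in spikes/s; negative values indicate
inhibition.  Windows are half-open — spontaneous [−0.5, 0), stimulation
[0, 0.5) — so a spike exactly at onset counts as evoked.  Repeated
presentations of the same (sensillum, neuron, compound, dose) are retained
as repeated measures and flagged.

## Synthetic data

**Flights** are a correlated random walk with an advective upwind bias:
per-frame heading rotations from an AR(1) turn-noise vector (persistence
0.7, stationary sd 3°/frame/axis), a per-frame blend of the heading toward
the upwind axis (weight = `upwind_bias`), Gaussian speed noise around
30 cm/s, reflection at the walls, and screen interaction: on contact, with
probability `bounce_prob` the agent dwells in the 6 cm screen zone for an
exponential time (mean `bounce_dwell_s`), otherwise it reflects.  Saccades
arrive as a Poisson process; each rotates the heading about a random
perpendicular axis with a raised-cosine angular-velocity pulse of exactly
the stated peak (default 3000 deg/s) and width (default 5 frames, ~100°
total turn).  Cruising noise and the upwind blend pause while a pulse is
active, so the injected turn is what the detector measures (minus a
deterministic ~25% discretization loss from central differencing, which
still leaves the measured peak near 2250 deg/s, above threshold).

`mean_airborne_s` is defined as the group-mean *active* flight time —
frames inside the filmed volume and outside the bouncing zone — drawn per
animal from a gamma distribution with shape 2 (positive and right-skewed,
matching how airborne-time distributions look in practice).  The simulation
runs until the drawn active time is reached, so the flight-duration metric
estimates this parameter directly and preset ratios propagate to the
pipeline unchanged.  Two presets encode the study conditions: teneral-like
(response probability 0.45, 12 s mean active time, 0.5 saccades/s, weak
upwind drive, little bouncing) and mature-like (0.85, 32.4 s — 2.7 × 12 —
1.0 saccades/s, stronger drive, frequent bouncing).

**Spikes**: each sensillum draws a Gaussian intercept (sd 8 Hz) added to a
20 Hz baseline; window counts are Poisson with the stimulation rate raised
by `genotype_scaling × (40 + 15 · (log10dose + 3))` spikes/s, truncated at
zero (truncations are counted).  `genotype_scaling` = 1 is wild-type-like,
0 abolishes the evoked response (knockout-like), 0.5 is intermediate.
Spike times are uniform within their windows.  Both generators are
bit-reproducible under a fixed seed.

### What the synthetic data does and does not show

The generators reproduce the *statistical structure* the pipeline assumes —
saccadic bouts above threshold, boundary dwells, group differences in
response probability and airborne time, dose-dependent evoked rates with
sensillum-level heterogeneity — with known ground truth, so recovery tests
demonstrate the pipeline's correctness, not biological realism.  Known
gaps:

* no aerodynamics, plume structure or odour-gated behaviour; upwind drive
  is a constant blend, not odour-triggered surge/cast;
* saccade pulses are stereotyped; real saccades vary in amplitude and
  co-vary with speed;
* dead-time: two injected pulses closer than ~4 frames merge into one
  supra-threshold bout, so detected frequency underestimates the injected
  Poisson rate by roughly `rate × 4/fps` (~8% at 1.2 saccades/s).  This is
  intrinsic to threshold-bout counting, not an implementation error; the
  recovery test evaluates the estimate against per-flight Poisson
  variability, which dominates this loss;
* the sensillum intercept enters both spike windows and cancels in the
  baseline-corrected rate, so the fitted random-intercept variance of the
  mixed model is near zero on simulator output (flagged `singular`, and
  the genotype F test is conservative there).  Real repeated-measures
  heterogeneity affects the evoked response itself; the mixed model's
  calibration is therefore verified against its own data-generating null.

## Problem sizes used in the shipped checks

The duration-ratio recovery pools ten seeded runs of 30 released animals
per preset (600 trials); calibration checks use 1000 replicates each; the
detector is compared against a brute-force oracle on 1000 random series.
These sizes put Monte-Carlo noise well inside the stated tolerances while
keeping the whole suite runnable on a laptop in a few minutes.
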