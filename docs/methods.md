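# Methods

This note documents the models and procedures implemented in `canopycc`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Segmentation and index extraction

A pixel is vegetation iff its hue lies in an inclusive window, saturation
strictly exceeds `sat_min`, and value is strictly below `val_max`
(defaults 50–180°, 0.1, 0.95).  Hue bound strictness is not dictated by the
rule's usual statement, so we fix it as inclusive-hue / strict-S / strict-V
and cover the convention with oracle tests against a per-pixel stdlib
(`colorsys`) implementation.  When `hue_min > hue_max` the window wraps
through 0°, which is how red-purple foliage (hue near 350°) is admitted;
the red archetype carries a 300–40° override window.  Conversion uses the
standard hexagonal RGB→HSV mapping (`skimage.color.rgb2hsv`), hue reported
in degrees.  No gamma correction and no morphological cleanup by default;
an optional despeckle (drop vegetation pixels with no vegetation
8-neighbour) is off by default.

The per-image index is the chromatic coordinate of the **masked mean DN**
(ratio of means), the common phenocam convention.  A mean-of-per-pixel-
ratios variant exists for sensitivity checks; the two agree exactly on
uniform regions and differ in general.  `Y_CC` is computed from the
per-image `G_CC` and `R_CC`, consistent with the ratio-of-means choice.
Replicates are averaged (unweighted) after index computation when
aggregating to treatment level.

## A chromatic feasibility constraint worth knowing

Any pixel admitted by a hue window in which one channel is maximal has that
channel's chromatic coordinate **above 1/3** (at hue 60–180°, green is the
max channel, so per-pixel `G_CC ≥ 1/3`; the bound degrades only slightly at
the 50–60° margin).  Consequently a masked-mean `G_CC` far below ≈ 0.33 is
not observable under a green-window segmentation — large multiplicative
reductions of a dominant index (say 40 % from a peak of 0.414) push foliage
hue out of its own segmentation window as leaves brown.  The package
handles this explicitly:

* default archetypes floor the stressed dominant index at
  segmentation-compatible values (`index_floor` ≈ 0.35–0.36), so default
  pipelines produce response ratios of realistic magnitude (≈ −0.15 to
  −0.25) and never empty masks;
* stress-recovery scenarios (`experiments.drought_reduction_scenario`)
  lower the floor and extract with a wide wrapped window
  (300–180°, i.e. everything but blue-cyan) over backgrounds that fail the
  saturation/value tests, so the full imposed reduction (40 % green, 35 %
  red) is recoverable through the pipeline and is verified to ±5 points.

## Synthetic experiment generator

The generator defines the study conditions; its defaults are fixed, not
tuned per run.

**Design.**  Species × treatment × period × replicate factorial:
3 × 3 × 3 × 3 = 81 plots with treatments (full, rainfed, drought), and a
four-treatment variant adding deficit irrigation (108 plots).  Treatment
periods coincide with the growth stages; outside its period a plot follows
the well-watered baseline regime.

**Seasonality.**  The unstressed dominant index follows a double logistic
in day of year, `baseline + amplitude · σ(r_s(d − m_s)) · σ(−r_a(d − m_a))`,
with the amplitude normalized so the seasonal maximum equals the archetype's
`peak`.  Defaults: rise midpoint DOY 100, decline midpoint DOY 250, rates
0.07/0.05 d⁻¹, giving a peak near DOY 165.  Peaks: green 0.414, yellow
0.417, red 0.419; baselines 0.336–0.372.

**Soil water content.**  Per-plot AR(1) series at the photo cadence
(10 days), stationary around the treatment mean with regime means
full 65 %, deficit 40 %, rainfed 32 % (+ Poisson-count exponential rain
pulses, rate 0.25/step, mean 10 %), drought 18 %; AR coefficient 0.6,
clipped to (0.5, 99.5).  SWC is an abstract percentage; volumetric vs
field-capacity semantics are left to the caller.

**Stress coupling.**  `stress = clip((60 − SWC)/(60 − 20), 0, 1)`, so full
irrigation gives ≈ 0 and severe drought ≈ 1.  The dominant index target is
`seasonal(d) · (1 − sensitivity · stress)`, floored as above.  Default
sensitivities: green 0.40, red 0.35, yellow 0.10 — chosen so the imposed
effect sizes match the headline reductions the analysis should recover, and
so the yellow archetype's whole-season CV stays well under 15 %.

**Leaf color.**  Each archetype has a hue schedule mapping the target index
to foliage hue (green 100° → yellow-brown → brown near 10° as the index
falls; red 340° → brown 25° → faded green 130° below the 1/3 boundary;
yellow pinned near 60°).  Given hue, the saturation that makes the
normalized dominant channel hit the target exactly is solved by Brent root
finding (the dominant proportion is monotone in saturation at fixed hue);
in a hair-thin infeasible band at the 1/3 crossing the hue is nudged by the
smallest feasible offset.  The scene is rendered at HSV value 0.45–0.55
with per-pixel hue jitter (sd 1.5°), multiplicative illumination jitter
(sd 4 %, chromatically neutral), additive DN noise (sd 3), and 8-bit
quantization.  Background pixels (default 35 %) come from color models
that each fail one branch of the default rule: soil (120, 80, 40) fails
hue (30° < 50°), bright equipment (250, 250, 252) fails value, gray cover
fails saturation.  With all noise zeroed, the segmentation mask equals the
ground-truth mask exactly and the extracted coordinates reproduce the
target within 1/255 per channel.

**Traits.**  SPAD and specific leaf area decline linearly in stress within
species bounds (SPAD 10.6–102.7 overall; SLA tops 60.2–125.5 well-watered,
floors 13–17 under drought), with truncated Gaussian noise.

**Reproducibility.**  One master seed; every plot × date × purpose draws
from a `SeedSequence` keyed by CRC32 of stable identifiers, so subsets are
reproducible and whole runs are byte-identical for a fixed seed.

**Not emulated:** radiometric camera effects (exposure, white balance,
vignetting), 3-D canopy geometry, shadows and speculars, real weather, or
spatial correlation between neighbouring pixels.  Passing tests show the
*pipeline* is correct and calibrated under these idealized conditions; they
are not evidence about any particular field dataset.

## Response analysis

`RR = ln(B_s/B_ns)` is computed on treatment-level replicate means at
exactly matching DOYs (both the protocol and the generator share a 10-day
grid, so no interpolation); per-replicate RR is available via the plot-level
series when uncertainty is wanted.  CV uses the sample (n−1) standard
deviation over the whole-season treatment-level series.  Stage means are
unweighted within the inclusive stage calendars.

## Inference

The ANOVA is a balanced fixed-effects decomposition — species, season
(growth stage) and treatment as main effects, replicate as an additive
blocking factor — fitted by OLS (`statsmodels`), with partial
η² = SS_effect/(SS_effect + SS_error).  A full repeated-measures/REML mixed
model is deliberately out of scope: the additive block reproduces the same
reporting surface (df, MS, F, p, partial η²) on balanced data without
variance-component estimation.  Unbalanced input is rejected (naming the
offending cells) rather than silently choosing a sums-of-squares type.
The analysis unit is one plot-stage mean per plot, avoiding
pseudo-replication of the 10-day time series.  Tukey HSD uses the
studentized range distribution at the pooled (or supplied) error term;
with two groups it reduces exactly to the pooled t-test, which the tests
assert, and p-values print as `<0.001` below that level.

## SWC thresholds

The quantitative link "keep index criterion `c` ⇒ need SWC ≥ s*" is
estimated by fitting a monotone response of plot-stage mean index to
plot-stage mean SWC.  Primary family: four-parameter logistic
`lower + (upper − lower)·σ(rate·(SWC − mid))` with `rate > 0` enforced by
bounds and `upper ≥ lower` by a span reparameterization
(`scipy.optimize.curve_fit`); on optimizer failure the fit falls back to
isotonic regression with linear interpolation, and the family used is
recorded.  Inversion is closed-form for the logistic and bisection on the
isotonic interpolant; a criterion at/above the upper limit is flagged
unachievable (not an error), one below the curve at the domain minimum
returns the domain minimum.  Uncertainty is a plot-level percentile
bootstrap (≥ 200 resamples, ≥ 8 plots); estimates with > 50 % unachievable
resamples are flagged unreliable.  Percentile (not BCa) intervals are used
for transparency at these sample sizes.  In the pipeline the criterion
defaults to 95 % of the control-treatment level, because absolute criteria
such as "R_CC > 0.8" are outside the chromatically feasible range of
masked means (see the 1/3 constraint above).

## Numerical choices

* logistic fit: `p0` from data extremes, bounds lower ∈ [−0.5, 1.5],
  span ∈ [0, 2], mid within ±100 % SWC of the data, rate ∈ [10⁻⁴, 10];
  `xtol = ftol = 1e-12` so noiseless parameters recover to 1e-6;
* degenerate inputs are errors, not NaNs: empty masks, zero-sum DN,
  constant covariates, constant responses, zero within-group variance,
  unbalanced ANOVA cells, < 5 distinct SWC values;
* DN arithmetic in float, images clipped and rounded to uint8 once, at the
  end of rendering; quantization tolerance in exactness tests is 1/255;
* CSVs are written with ISO-8601 dates and dot decimals; reading them back
  for byte-identical round trips requires pandas'
  `float_precision="round_trip"` parser.

## Problem sizes used by the test-suite and acceptance script

Simulation studies run at sizes chosen to make the Monte-Carlo error small
relative to the tolerance being checked: 32×32 px oracle scenes (100
random images), 24×24 px canopy scenes for effect-recovery runs (50 seeded
runs, 3 replicates), 1000 null + 400 alternative tables for F-test
calibration, and 100 repetitions for threshold recovery.  The full
standard-year pipeline (81 or 108 plots × 19 dates at 48×48 px) runs in
seconds.

## Known limitations

* The stress–color coupling is a single multiplicative factor on the
  dominant index; real canopies change hue, coverage and architecture
  jointly.
* Thresholds assume a monotone SWC–index relationship within the observed
  SWC span; hysteresis and lag (color responding to past drought) are not
  modelled — stress follows the current SWC reading.
* The ANOVA treats season as a fixed factor on plot-stage means; temporal
  autocorrelation within a stage is ignored by design.
* Default-window pipelines understate large drought reductions (floors and
  the 1/3 constraint); use the wide-window stress scenario when the true
  effect size is the quantity of interest.
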