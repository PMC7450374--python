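# Methods

This note documents the models, conventions and numerical choices behind
`glycosurv`, and what the test suite does and does not establish.

## Data model and import conventions

One patient-year is an event log of glucose samples (SMBG/CGM, mg/dL),
insulin doses (bolus/basal, U), carbohydrate intakes (g) and self-reported
infection episodes (onset date, duration in days, free-text label).
Timestamps are minute-precision local clock time; no time-zone arithmetic is
attempted (diary apps record wall-clock time; a DST-duplicated timestamp
keeps its first occurrence). Import applies a glucose plausibility gate of
[20, 600] mg/dL — bracketing common CGM device limits, since no gate is
standard in the literature — and collapses exactly duplicated rows; both
actions are counted in a validation report and never modify values. A zero
insulin dose is legal but counted. Import is fatal only for a missing
column or when more than 10% of timestamps fail to parse.

## Preprocessing chain

1. **Resampling.** Events are assigned to half-open bins
   `[start, start+width)` by timestamp truncation (a 23:59 dose stays in
   its calendar day), with width 1 h or 1 d. Glucose samples in a bin are
   averaged (SMBG and CGM pooled); insulin and carbohydrate entries are
   summed. Bins with no glucose are *missing*; bins with no insulin/carb
   entries are true zeros, because the logs are event streams and absence
   means no intake. Resampling therefore conserves stream totals exactly.
2. **Imputation.** Missing glucose bins (hourly work only) are filled by a
   natural cubic spline over bin index, requiring at least 4 known bins;
   leading/trailing gaps take the nearest known value. Imputed bins are
   flagged. Insulin and carbs are never imputed.
3. **Smoothing.** Every channel is smoothed by a *trailing* moving average,
   default window 48 h (window = N bins, the current bin plus the N−1
   preceding ones). Head-of-series windows are shortened so output length
   equals input length. The trailing form trades delay (~1 day at the
   48 h default) for causality: the smoothed value at t depends only on
   bins ≤ t, which matters for a detector meant to run in real time.
4. **Ratio.** The bolus-to-carbohydrate ratio (and the basal analogue) is
   computed from the *smoothed* insulin and carbohydrate series — never
   bin-wise on raw data, where hourly carb-free bins would divide by zero.
   Where smoothed carbs are zero the ratio is undefined (NaN, flagged);
   defined values are guaranteed finite.

## Weekly deviation statistics

For an episode with onset day `o`, three windows are compared on raw daily
aggregates: preinfection `[o−7, o)`, infection `[o, o+7)` and postinfection
`[o+7, o+14)`. Anchoring on the self-reported onset is a convention (the
onset date is the only anchor the data offer); a configurable day offset is
provided. Weekly statistics are the mean and sample SD (n−1) of daily
values and need at least 4 covered days. Deviations are reported as
percentage *increase* for glucose, insulin and ratio and percentage
*reduction* for carbohydrate, always against the flanking-week mean as
denominator; values are rounded to two decimals for reporting with the
unrounded value kept internally. Cross-case aggregation is the unweighted
arithmetic mean of per-case percentages, per parameter and reference side.

The ratio shift of an episode is measured against the patient-year's
*normal operating point* — the mean smoothed daily ratio over all
non-infection days — rather than a flanking week, because the ratio is the
slowest-moving and most person-specific of the four parameters.

The five published reference cases ship as week summaries
(`synthetic_data.reference_cases`). Two published per-case figures
disagree with arithmetic on the published means: the third case's
glucose-vs-pre (printed 7.26, means give 5.25) and the fourth case's
carbs-vs-post (printed 35.34, consistent with an infection-week
denominator; the flanking-week convention gives 26.11). The package
reproduces the means' arithmetic and exposes
`flag_discrepancies` to surface such inconsistencies; it does not match
them.

## Density estimation

Both estimators use Gaussian kernels with Abramson's square-root law for
adaptivity: a fixed-bandwidth pilot estimate is evaluated at the sample
points and each kernel width is scaled by λᵢ = √(g / pilot(xᵢ)), g the
geometric mean of pilot densities. The adaptivity scheme is our choice;
"adaptive KDE" alone does not pin one down, and Abramson's is the standard
two-stage variant.

Bandwidths:

- **1D (ratio):** the diffusion plug-in selector of the improved
  Sheather–Jones family — fixed-point iteration on DCT-based estimates of
  the smoothness functionals over 2^14 bins, ℓ = 7 stages, root bracketed
  by `brentq` with an expanding upper bound. It avoids normal-reference
  rules and so does not oversmooth the bimodal full-year ratio sample
  (baseline band plus infection bump). The sample is standardised
  internally, which makes the selector scale-equivariant and
  translation-invariant to rounding error. If no bracket is found the
  normal-reference rule `σ(4/3n)^{1/5}` is used with a warning.
- **2D (glucose × ratio):** per-axis rule of thumb `hᵢ = σᵢ n^{−1/6}` with
  robust scale `min(SD, IQR/1.349)`.

Grids default to 2^10 points (1D) and 128×128 (2D), spanning the data
padded by 3 final kernel widths, so trapezoidal integrals land within 1%
(1D) / 2% (2D) of unity; these bounds are asserted as invariants. With
adaptivity off, the estimator is exactly the brute-force kernel mean, which
the tests check pointwise at 1e−10 (1D) / 1e−8 (2D).

**Distribution comparison.** The baseline estimate is fitted on daily
smoothed values with every reported infection day removed; the full
estimate uses all days. The published comparison is visual; we
operationalise it as `excess_tail_mass` — the fraction of full-data samples
above the baseline's 99th-percentile abscissa (definitionally ≈ 0.01 under
self-comparison) — plus the maximum observed value against the baseline
support. The tail quantile is configurable.

## The synthetic patient-year generator

Real multi-year logs with annotated infections are private, so the
generator defines the study conditions for every stochastic test. It
couples a behavioural layer to a one-compartment hourly glucose balance:

    BG[t+1] = BG[t] + k_c·CH[t] − φ(t)·k_i·IN[t] + EGP(t)
                    − k_d·(BG[t] − target) + ε[t]

with k_c = 3 mg/dL per g, k_i = k_c / ρ₀ (so the steady-state meal ratio is
the configured operating point ρ₀), k_d = 0.15 h⁻¹ and process noise
ε ~ N(0, 3 mg/dL). A deliberately simple difference equation replaces
physiological ODE models: the pipeline needs realistic aggregate
statistics, not metabolic fidelity. Basal insulin is logged but carries no
dynamics (it offsets unmodelled fasting hepatic output); physical activity
is fixed at zero, as the emulated logs have no activity stream.

Behaviour: 3–5 meals/day between 07:00 and 21:00, daily carbohydrate
N(200, 40) g split by a Dirichlet draw, meal boluses ρ·carbs with 10%
dosing noise, corrections at meals when glucose exceeds target + 20 mg/dL,
CGM samples every 60 min with N(0, 15) sensor noise and 5% dropout.

An infection episode scales three latent effects by a piecewise-linear
intensity ramp (0.7 at onset → 1.0 mid-episode → 0.35 at resolution;
symptom onset is abrupt, recovery gradual): insulin sensitivity
φ = 1 − 0.5·I, hepatic boost EGP = 4.5·I mg/dL/h, appetite factor
1 − 0.28·I. The simulated patient *chases* the extra insulin need — the
per-gram need rises to (1 + EGP·24/(k_c·CH))/φ — but delivers only a
`compensation` = 0.85 fraction of the excess. That partial chase is what
produces the empirical signature (elevated glucose despite more insulin
and fewer carbohydrates). Default effect sizes were calibrated, over 20
seeds, to land inside the envelope observed across the five published
cases: infection-week glucose +2–20%, bolus +20–60%, carbs −15–30%, and a
mid-episode smoothed ratio peak in 0.3–0.6 from a ρ₀ = 0.15 baseline; no
published quantitative values for φ or the hormonal boost exist to
calibrate against physiology. Identical configs (including seed) produce
byte-identical logs, and per-day ground truth (infection flag, φ, EGP,
intended vs delivered bolus) accompanies every simulation.

What the generator does **not** emulate: meal-absorption and
insulin-action kinetics (both instantaneous at the hourly step), exercise,
emotional-stress confounders, sensor drift or compression artefacts,
device changes mid-year, and multi-patient population structure. Passing
tests therefore show that the pipeline recovers the infection signature
under clean, well-specified conditions — not that the detector is
field-ready.

## Detection

Scores are computed per day against a personalized baseline — an adaptive
KDE of the ratio on infection-free days (≥ 50 required). Two bases:
`ratio_tail`, max(0, (ratio − q99)/q99) relative exceedance of the
baseline's 99th percentile; and `density_loglik`, −log baseline density
shifted so the baseline median scores zero. Days with undefined ratio
carry the previous score forward, flagged. Status: infected (1) requires
the score at or above the upper threshold on ≥ 2 consecutive days (a
single spike is at most suspicious, −1); the rule is monotone in scores.
Crisp thresholds with persistence stand in for the fuzzy alarm logic a
deployed system would fit per user; the defaults (0.1, 0.25) on the
`ratio_tail` basis were tuned on held-out simulation seeds and give mean
per-day sensitivity ≈ 0.85 at zero measured false-positive rate over the
calibration battery. The prediction-model branch (residual/conformal
scoring) is an interface placeholder, not implemented.

Evaluation is per-day against simulator truth: sensitivity (fraction of
episode days flagged 1), false-positive rate (fraction of other days
flagged 1) and latency (first flagged day minus first onset). Because the
48 h trailing smoother delays the signal, roughly the first episode day is
undetectable in principle and a ~1–2 day tail after resolution may stay
flagged; both are properties of the smoothing choice, not bugs.

## Problem sizes and test design

Stochastic guarantees (simulator envelope, detector recovery, null-year
false alarms, density tail control) are asserted on means over 20 seeded
patient-years of 365 days — large enough that seed-to-seed variation in
the mean is a few percent of each band's width, small enough that the full
suite runs in under a minute on one CPU. Exact guarantees (brute-force KDE
equality, conservation, causality, shift equivariance, scale equivariance)
use small deterministic instances. Published-figure reproductions run the
printed week means through the same operations used for simulated data.
The spline imputation oracle masks 10% of a noisy sinusoid-plus-trend
series and bounds the mean absolute error against the clean signal by the
noise SD. The null-case deviation bound is on the mean absolute
placebo-week percentage across parameters and seeds: at the configured
daily carbohydrate SD (40 g), single weekly contrasts can legitimately
exceed 10% — the published flanking weeks themselves differ by that much.

## CLI

The interface mirrors the module boundaries
(`simulate`, `preprocess`, `weekly`, `density`, `detect`, `report`). All
outputs are CSV/JSON; every command writes a manifest with its parameters
and the package version, refuses to overwrite without `--force`, and is
deterministic given its inputs. Plot generation is deliberately out of
scope; the exported tidy CSVs are plot-ready.
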