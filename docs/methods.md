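# Methods

This note documents the models, numerical choices and limitations behind
`abmiref`, in the order the pipeline runs them.

## The index and its exponent schedule

The allometric body mass index is `ABMI = weight_kg / height_m^p`, with
`p = p_t(age, sex)` a tabulated exponent that rises from ~2.2–2.3 at 5 y to
~3.0–3.1 around puberty and returns to the isometric 2 by 18 y (boys) /
16 y (girls). The packaged table stores the exponents alongside the L/M/S
rows at 6-month steps.

Exponent lookup is **piecewise constant and right-continuous**: a query age
maps to the entry at the greatest tabulated age ≤ the query, and any age
past the last row returns exactly 2. The exponents are published as
discrete per-age values; interpolating between them would fabricate
unpublished exponents, so we deliberately do not.

`estimate_exponent` reproduces the estimation recipe for new data: within
an age–sex stratum, weights and heights beyond ±2 SD of the stratum mean
are trimmed once, then the exponent is the OLS slope of log(weight) on
log(height). `smooth_exponents` smooths per-age slopes with a cubic
regression spline whose 5 interior knots sit at age quantiles (the knots
are data-driven, not fixed a priori), evaluates it on the 6-month grid, and
clamps ages at or beyond each sex's isometric age to 2.

## Reference tables and interpolation

A `GrowthReference` holds per-sex L/M/S rows over age; the packaged table
spans 60–240 months. Between printed rows each curve is interpolated
independently with **shape-preserving piecewise-cubic Hermite (PCHIP)**
polynomials: printed rows are reproduced exactly, and interpolated values
never overshoot the bracketing rows — important on the steep pubertal
segment of the M curve, where an unconstrained cubic spline would ring.
Ages outside the printed span raise an error; the table is never
extrapolated, because the reference is undefined there.

The reference CSV dialect is UTF-8, comma-separated, `.` decimal, header
`sex,age_months,L,M,S[,p]`; numeric cells are written at 4 decimals (the
printed precision), so load→write round-trips the packaged file
bit-exactly.

## LMS z-scores

`z = ((y/M)^L − 1)/(L·S)` with the log branch taken when `|L| < 1e−12`
(the analytic limit; the continuity of the two branches is
property-tested). The inverse transform is exact; a z outside the
distribution's support (`1 + L·S·z ≤ 0`) raises rather than silently
clamping. Centile curves for distinct z-levels never cross because the
inverse is strictly increasing in z at every age.

## Cleaning cascade

Stages run in a fixed order — eligibility, missing data, height decreases,
implausible values, sparse age-months, population-level weight outliers,
individual-level BMI outliers — each logged with subjects/observations
removed, and the report conserves counts exactly.

Boundary semantics follow the rules' wording literally: "below −X or above
+X" removes strictly beyond X, while a height decrease of exactly 0.5 cm
*is* flagged ("≥ 0.5 cm"). Height decreases compare each measurement with
the running maximum of earlier ones, so a drop relative to any previous
sweep counts. Implausibility (|HAZ| > 6, |BMI z| > 5) removes whole
subjects, matching a subject-level accounting of that screen; the
screening reference is user-supplied because no single canonical source
covers every cohort — tests use a synthetic one consistent with the
generator.

The individual-level screen fits a linear mixed-effects model of BMI
(statsmodels `MixedLM`): fixed effects a sex-specific cubic in age, random
intercept and slope per subject. Observations deviating more than 2 SD
from the subject-specific prediction are removed. The SD used is the
**empirical SD of the deviations**, not the model's residual sigma: BLUP
predictions shrink residuals, so scaling by sigma would systematically
under-flag (the observed null flag rate matches the nominal
2·Φ(−2) ≈ 4.6% only with the empirical scaling). Subjects with a single
observation are scored against the population-level prediction. The cubic
fixed-effect structure is the simplest that tracks the age trend; the
model statement in the source methodology names only "a linear
mixed-effects model", so this structure is a documented package choice.

## BCCG fitting (the LMS engine's inverse problem)

The age-conditional law is Box–Cox Cole–Green: `z(y; μ, σ, ν)` standard
normal truncated to the positive-y branch, giving

```
log f = (ν−1)·ln y − ν·ln μ − ln σ − z²/2 − ln√(2π) − ln Φ(1/(σ|ν|))
```

The truncation normalizer is kept in all reported likelihoods (the density
integrates to 1 by quadrature to ~1e−10) but omitted from the scoring
derivatives used in fitting, where its gradient is O(1e−7) at realistic
(σ, ν); the same omission is conventional in GAMLSS scoring.

Each parameter curve is a cubic B-spline with 20 equally spaced interior
knots and a second-order difference penalty. Links: identity for μ and ν,
log for σ; invalid candidate states under the identity links are rejected
by step-halving. Fitting is cyclic penalized Fisher scoring
(Rigby–Stasinopoulos): per parameter, a weighted penalized least-squares
update of the spline coefficients with expected-information weights
(`(1+2σ²ν²)/(μ²σ²)` for μ, `2/σ²` on the log scale for σ, `7σ²/4` for ν),
with step-halving so the penalized deviance never increases. Outer cycles
stop when the penalized deviance changes by < 1e−4 (cap 200 cycles).

**Degrees of freedom.** A requested df counts flexibility beyond a
baseline: total effective df (trace of the smoother) = df + 2 for M and S
(constant + linear baseline; df = 0 is a straight line in age) and df + 1
for L (df = 0 is a constant skewness, fitted as a scalar; df = 1 a linear
one). Baseline cases use exact unpenalized polynomial designs; penalized
cases tune λ by bisection on log-λ until the trace edf is within 0.05 of
target, re-tuning during the first three cycles and freezing afterwards
(so the monotone-deviance guarantee applies to the frozen objective).
`BIC = −2·loglik + ln(n)·(total edf)` holds as an exact invariant of every
returned fit; `select_df` fits the full grid (2×5×4 = 40 triples by
default), takes the minimum BIC, and breaks ties within 1e−9 toward the
smaller total df.

Initialization is deterministic and robust: μ from binned running medians,
σ from the binned MAD of log y, ν = 0.

With the default df (1, 4, 3), recovery experiments that simulate 100
draws per month from the packaged boys' curves put the fitted M within
about 2% of truth over 72–228 months; the residual is mostly smoothing
bias at the steep adolescent segment, where an edf-6 P-spline is at the
edge of what the curvature demands, and the expected-information weights
(∝ 1/(μσ)²) further down-weight the oldest ages. Values across seeds
straddle 2% (≈1.7–2.4%).

## Cutoffs

A cutoff anchors an adult index value (17, 25, 30 kg/m²) at a late
adolescent age — 204/216/228/240 months for girls, 216/228/240 for boys
(girls' growth stabilizes earlier, justifying the extra 17-y anchor) —
converts it to z\* there, and traces that quantile over all ages. All
three values are derived at every anchor age (21 sets), a superset from
which users select; the curve passes through its anchor by construction
(checked to 1e−6).

## Worm plots

z-scores are split into equal-count age bins (equal counts, not equal
width, keep the cubic fits stable where ages are sparse); per bin the
sorted z are compared with normal order-statistic expectations at Blom
plotting positions, and a cubic in the theoretical quantile is fitted to
the deviations. Coefficients flag misfit at the van Buuren–Fredriks
conventions: |b0| > 0.10, |b1| > 0.10, |b2| > 0.05, |b3| > 0.03 (the bin
count and thresholds are conventions of the cited diagnostic, configurable
by the caller). Under a correct reference with 1000 z per bin the null b0
has SD ≈ 0.025, so the 0.10 flag threshold is a ≈4σ event per bin.

## Synthetic cohorts

The generator emulates the structure of the longitudinal surveys such
references are built from, inside the 60–240-month reference span: five
survey entries (two multi-country cohort patterns, one national cohort
pattern, two school cohorts including a 3-sweep high-school arm) with
fixed sweep ages jittered ±3 months, five ethnic groups crossed with sex
and survey, and a latent z per occasion `z_t = u + e_t` with subject level
`u ~ N(0, τ²)`, AR(1) occasion noise of marginal SD σ_e and correlation ρ
across sweeps, and τ² + σ_e² = 1 so the marginal z is exactly standard
normal — the reference's S is then the sole dispersion source and
generated quantiles match the reference in expectation. Defaults τ² = 0.6,
σ_e² = 0.4, ρ = 0.3 give within-subject z correlations of ~0.6–0.7 between
adjacent sweeps, in the range reported for BMI-z tracking over multi-year
gaps.

Heights come from a saturating-ramp median curve per sex (linear ~0.48
cm/month in childhood, levelling to 177/163 cm by ~17/15 y), a
multiplicative subject offset (SD 4%) and 0.1 cm occasion noise, after
which each subject's heights are made non-decreasing (running maximum):
stature does not shrink at these ages, and this guarantees the
height-decrease screen has a zero false-positive rate on clean subjects by
construction. Weight is reconstructed as `index · height_m^p`.

Contamination is injected with mutually exclusive per-record labels:
height decreases set a later sweep 0.5–3 cm below its predecessor
(violating the screen by construction); implausible values move BMI to
z = −8 of the screening reference (the BCCG upper tail has no z = +8
support at the reference's negative skewness, so the low side is used);
missingness blanks one core field; weight outliers move a record to its
(sex × 6-month) stratum mean ± 3 internal SD. Because a −3 SD weight is
also BMI-implausible, low-side weight outliers are typically caught by the
earlier implausibility screen — an intended property of the ordered
cascade, and why stage-level recall is evaluated among records that reach
the stage.

What the generator does **not** emulate: attrition, secular trends,
ethnicity-specific effect sizes, measurement digit preference, or real
survey age distributions. Passing tests therefore demonstrate the
pipeline's correctness under its stated statistical assumptions, not
performance on any particular real cohort.

## Problem sizes

The test suite and acceptance script use desk-scale sizes chosen to make
Monte-Carlo checks sharp while staying quick: 100 draws/month (n = 18 100)
for single-fit recovery, 50 draws per 3-month step (n = 3 050) for the
40-fit BIC grid, cohorts of ~400–2000 subjects for cleaning and
generator checks, and 16 × 1000 z-scores for worm-plot calibration.

## Known limitations

- The fitter covers the BCCG/LMS family only (no extra distributions or
  covariates beyond age); age enters untransformed.
- The edf-matching df convention is one defensible reading of
  "penalized-spline df" grids; software differs in whether the linear
  baseline is counted, and fits at the same nominal df can differ
  accordingly.
- Exponent estimation treats the log-log slope as the allometric exponent;
  when height and weight are mutually dependent the true exponent can
  exceed the regression slope (attenuation), which is inherent to the
  recipe, not corrected here.
- The cleaning cascade's implausibility screen depends on the
  user-supplied screening reference; with a poorly matched reference the
  ±6/±5 limits change meaning.
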