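# Methods

## Model

Base excess is modeled by the computational (Van Slyke type) form

    BE(β) = (HCO3⁻ − 24.8 mmol/L) + (pH − 7.40) · β,

with β the whole-body buffer power in mmol/L per pH unit.  Bicarbonate,
when not supplied, follows Henderson–Hasselbalch at 37 °C,
HCO3⁻ = S·PCO2·10^(pH−pK′) with pK′ = 6.1 and S = 0.0307 mmol/L/mmHg;
both constants are configurable (`AcidBaseConstants`) because source
tables sometimes carry analyzer-derived HCO3⁻ computed with slightly
different constants.  When a row carries both a measured HCO3⁻ and
(pH, PCO2), the measured value is used and a warning is logged if it
disagrees with the derived value by more than 1.0 mmol/L (configurable).
All pressures are mmHg and concentrations mmol/L; kPa input is
deliberately unsupported, since a silent unit switch would rescale β.

The central premise is *CO2-invariance at the true β*: for a subject
whose whole-body buffer power is β_true, an acute PCO2 change moves pH
along the in vivo buffer curve such that BE(β_true) stays at the
subject's metabolic baseline.  No mechanistic compartment model is
assumed; invariance is the minimal generative model under which the
zero-slope calibration below is consistent.  Renal compensation is out of
scope — every exposure is treated as acute.

## Calibration by test inversion

Because BE(β) is linear in β, the pooled OLS slope of BE(β) on PCO2
decomposes exactly as slope(β) = a + b·β, where a and b are the OLS
slopes of (HCO3⁻ − 24.8) and (pH − 7.40) on PCO2.  The sweep evaluates
slope(β) on an inclusive uniform grid (default 10,000 points on [5, 20],
step ≈ 0.0015) by exact OLS sufficient statistics, vectorized over the
grid; β* is the grid point minimizing |slope| (ties break to the smaller
β).  The 95% CI is obtained by test inversion — the set of grid β whose
slope CI (t distribution, residual dof) contains zero — reported as the
[min, max] of that set, flagged if empty (degenerate) or non-contiguous
(the inversion set is a quadratic condition in β and need not be an
interval).  When |b| < 1e−12 there is no zero crossing and the sweep is
flagged non-identifiable.  A delta-method CI for the analytic crossing
−a/b, using the joint sampling covariance of (a, b) (the two regressions
share a design column, so cov(â, b̂) = σ̂_uv/S_xx with σ̂_uv the residual
cross-moment), is reported alongside as a cross-check.

Pooled OLS ignoring within-subject correlation is the default estimator;
a cluster-robust-SE option exists but is off by default so that the
default path matches a single pooled regression per study.  Consequences
of this choice are quantified below.

## ANCOVA

Study heterogeneity is tested in the linear model
SBE ~ PCO2 + study + PCO2:study with dummy coding.  The slope test is
the joint F-test of all interaction terms.  The intercept test is the
joint F-test of the study main effects *within the full interaction
model*, with PCO2 centered at the grand mean: without centering that
test refers to an extrapolated PCO2 = 0 where it has essentially no
power against real baseline differences (a 2 mmol/L baseline shift gave
p ≈ 0.7 uncentered, p < 1e−10 centered).  Centering leaves the
interaction test and all slopes unchanged.  The main-effects-only
(reduced-model) intercept test is computed and reported alongside.  The
95% level and two-sidedness are defaults; no multiple-testing correction
is applied.

Per-subject SBE excursions are summarized against the lowest-PCO2
exposure as baseline (titrations are modeled as acutely ascending);
subjects with a single exposure are excluded with a warning.

## Synthetic data generator

`StudyDesign` defaults emulate an unanesthetized-volunteer chamber
study: 14 subjects, PCO2 levels 40/55/70/85 mmHg, β_true ~ N(12.1, 1.5²)
truncated at 0, baseline SBE ~ N(0, 1²), measurement noise 0.005 pH
units and 1.0 mmHg.  These defaults are the package's fixtures — the
historical studies published no distributional description of their
subjects, so the sds are chosen as typical blood-gas analyzer precision
and plausible inter-subject spread.  For each subject the noiseless pH
at each level is the unique root of BE(β_true) = baseline (bisection on
pH ∈ [6.5, 8.0] to 1e−10; the objective is strictly increasing in pH,
so convergence is guaranteed); noise is then added to pH and PCO2 and
HCO3⁻ recomputed from the noisy pair, mirroring the analyzer measurement
chain.  An option to perturb HCO3⁻ directly instead is available but off
by default.  Random streams are derived per study by stable hashing of
(master seed, study id) and per subject by spawned substreams, so adding
or reordering studies never changes another study's draws.

What the generator does *not* emulate: renal/temporal compensation,
drug and anesthesia effects, species differences beyond the parameter
values, analyzer drift, and any nonlinearity of the true buffer curve
beyond Henderson–Hasselbalch.  Passing recovery tests therefore show the
estimator is consistent and correctly implemented under the invariance
model — not that 12.1 is the right β for any particular patient.

## Known statistical properties (measured with this package)

Two properties of the spec'd estimator under the default study
conditions are worth stating plainly, both measured over 200 replicate
datasets:

- **Errors-in-variables bias.**  PCO2 measurement noise enters the
  regressor, so the zero-crossing estimate is biased upward: mean β̂ ≈
  12.36 for β_true = 12.1 at the default 1.0 mmHg PCO2 noise (unbiased,
  12.10, when only pH noise is present).  The bias is a property of
  regressing on the measured PCO2 — the method as defined — not of the
  implementation.
- **Conservative coverage.**  Subject-level heterogeneity (baseline sd
  1.0 mmol/L, β_true sd 1.5) inflates the pooled-OLS residual variance,
  widening the test-inversion CI (mean width ≈ 6 β-units vs a β̂
  sampling sd ≈ 0.8); empirical coverage of β_true is ≈ 1.00 rather
  than 0.95.  With measurement noise only, coverage is ≈ 0.90–0.95.
  A cluster-robust or mixed-model analysis would tighten this; it is
  deliberately not the default.

## Numerical choices

- Bisection (not Newton) for the pH root: guaranteed convergence on the
  monotone objective; ~54 iterations to 1e−10 pH.
- Sweep grid inclusive of both endpoints; argmin ties resolve to the
  smallest β; slope(β) computed from centered sums of products, matching
  per-β statsmodels OLS to < 1e−12 (tested).
- Plausibility bounds (pH 6.5–8.0, PCO2 5–250 mmHg) reject corrupt rows
  at ingestion with per-row warnings; the bounds are configurable, and
  the pure arithmetic functions accept widened bounds for non-clinical
  inputs.
- Reports serialize NaN as null and are byte-stable given identical
  inputs and configuration.

## Problem sizes

Default analyses use 14-subject, 4-level studies (56 observations per
study); replicate-based summaries (recovery bias, CI coverage, ANCOVA
power and null calibration) use 100–200 replicates, which bounds the
Monte-Carlo error on a rejection rate at about ±0.03 and keeps any
single summary under a few seconds of compute.
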