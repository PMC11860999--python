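# Methods

This note documents the model, the conventions, and the calibration choices
behind `evband`'s defaults, in pipeline order.

## Virtual cohort (`evband.cohort`)

Subjects carry sex, age and body weight.  Weight is drawn from a
sex-stratified log-normal distribution truncated to [35, 150] kg by
inverse-CDF sampling (the draw count is fixed, so cohorts are reproducible
from the seed regardless of truncation mass).  Sex is Bernoulli(0.5) and age
uniform on [40, 85] years; age is carried only as a covariate hook.

The default distribution parameters (`female: mu=4.0234, sigma=0.1891`,
`male: mu=4.3619, sigma=0.1663` on the log-kg scale) are **calibrated, not
estimated**: they were fitted once, against a large fixed base sample, so
that the default cohort reproduces four published population-level drug-use
summaries at the 1.25 and 0.75 mg/kg dose levels — the average whole-vial
quantity per administration of the capped label dose (≈ 90.2 mg at
1.25 mg/kg), the average band-table dose (≈ 76.5 mg), and the geometric mean
band/label dose ratios (≈ 0.910 and ≈ 0.906).  The fitted distribution has an
asymptotic mean weight of ≈ 68.3 kg.  At n = 500 the sample mean fluctuates
by ± 1–2 kg and all downstream quantities inherit that noise; tests therefore
check distributional properties at large n and the n = 500 summaries with
their published tolerances.

## PK engine (`evband.pkmodel`)

Linear two-compartment disposition with zero-order (30-minute) IV infusion.
Typical clearance and inter-compartmental clearance scale allometrically with
body weight (exponent 0.75), volumes linearly (exponent 1.0), all referenced
to 70 kg.  Inter-individual variability is log-normal: each subject
multiplies each typical parameter by exp(η), η ~ N(0, ω²), with exactly four
standard-normal draws consumed per subject so parameter streams stay aligned
whichever ω² are zero.

Concentrations are evaluated in closed form from the bi-exponential
unit-bolus solution (macro constants α, β and coefficients from k10 = CL/V1,
k12 = Q/V1, k21 = Q/V2) with infusion-phase and post-infusion terms summed
over dose events by superposition.  AUC over any interval is analytic.
Steady state over a cycle of length τ is exact: each exponential term of each
dose accumulates by the geometric-series factor 1/(1 − e^(−λτ)), and the
steady-state cycle AUC reduces to (cycle dose)/CL.  A brute-force
multi-cycle iterator (`exposure_metrics_iterative`) serves as a validation
fallback and raises `ConvergenceError` if cycle AUCs fail to settle.  The
test suite additionally checks the closed form against numerical ODE
integration to < 1e-6 relative error.

Four endpoints are computed per subject and regimen: first-cycle AUC,
first-cycle end-of-cycle trough (t = 672 h for monotherapy), steady-state
cycle AUC, and steady-state trough.

### Default PK parameters (calibrated placeholders)

`CL = 0.1002 L/h`, `V1 = 6.435 L`, `Q = 0.0083 L/h`, `V2 = 2.819 L` at 70 kg,
with ω² = {CL: 0.047, V1: 0.10, Q: 0.30, V2: 0.30}.  The typical values were
fitted (least squares on the log scale, typical subject at the cohort
geometric-mean weight and dose) to published exposure summaries for the
1.25 mg/kg monotherapy regimen: geometric-mean first-cycle AUC ≈ 2510
mg·h/L, steady-state AUC ≈ 2589 mg·h/L, and trough accumulation from ≈ 0.25
to ≈ 0.29 mg/L.  The ω² were then chosen from a response-surface scan to
match the AUC %CVs (≈ 22–23%) while keeping all variances pharmacologically
plausible.

Two limitations are deliberate.  First, these constants are
**non-authoritative**: they reproduce the targeted summaries but are not the
estimated registrational parameters; every report is watermarked
"non-authoritative parameters (calibrated placeholder)", and
`parse_nonmem_control` exists to transcribe an estimated control stream
(which flips the watermark).  Second, the published trough %CVs (≈ 99% first
cycle, ≈ 85% steady state) are not reachable in a plain two-compartment model
with plausible log-normal IIV — under this structure the trough CV saturates
near 86% before the AUC CVs and geometric means degrade — so the defaults
accept trough CVs of ≈ 86/82% rather than distort the variance structure.
Trough dispersion is reported but not used as a gate; the paired-design GMRs
are unaffected (see below).

## Regimens and accounting (`evband.regimens`)

The label regimen doses `level × min(weight, 100 kg)` mg.  The band regimen
assigns one fixed dose per body-weight band; bands are half-open
`[lower, upper)`, contiguous from 0 to ∞, with non-decreasing doses.  The
packaged tables (in `evband/data/band_tables.csv`) use cut-points
45/55/65/75/95 kg at all four dose levels, and every dose is an exact sum of
20/30 mg vials.

`vial_decomposition` finds the minimal whole-vial cover of a dose: least
total mg ≥ dose, ties broken by fewest vials, then by preferring larger vial
sizes.  It is validated against exhaustive search.

Drug accounting compares mg consumed per administration under both regimens.
The band regimen always consumes exact whole vials (that is its point).  For
the label regimen two conventions are implemented and always reported side by
side:

- `whole_vial_reference` (default): the label dose also consumes whole
  vials — the complete-spillage worst case.  Under the 20/30 mg formulary
  this rounds every prescribed dose up to the next multiple of 10 mg (minimum
  20 mg).  The calibration targets above are reproduced under this
  convention, and it is the convention used for the headline savings.
- `exact_mg_reference`: the label regimen consumes exactly the prescribed mg,
  i.e. savings measure only the dose-reduction component, excluding avoided
  spillage.

## Equivalence (`evband.equivalence`)

Simulations are **paired**: the same subjects with the same η draws are
exposed to both regimens.  With linear PK every subject's metric ratio equals
their dose ratio, so all four endpoint GMRs coincide exactly with the
geometric mean of per-subject dose ratios — a structural identity the tests
assert to machine precision, and the reason the four printed ratios per level
agree.  Equivalence requires every GMR inside 90–111% (bounds inclusive), a
conservative window treating the drug as having a narrow therapeutic range.
%CV is arithmetic (sd/mean) by default; a geometric convention is available.
Exposure evenness across the weight range is summarized by weight-quartile
medians of steady-state AUC; "flatness" is (max − min quartile
median)/population median.  At n = 500 this statistic is noisy (a max − min
of four sample medians); comparisons between regimens stabilize from
n ≈ 2000.

## Band-table design (`evband.band_designer`)

`design_bands` searches the grid of exact vial sums (20–200 mg).  For each
band it keeps candidates whose band geometric-mean exposure stays within
90–111% of the population reference exposure (`per_band_mode="population"`;
a stricter per-band-reference mode is available), picks the smallest, and
enforces dose monotonicity across bands; if the assembled table then violates
a global constraint (population GMR window, %CV increase ≤ 2 points), it
raises single band doses, cheapest expected-mg first, until feasible.  Dose
linearity makes candidate evaluation closed-form (per-mg exposure scale per
subject).  `design_bands_exhaustive` is the validation oracle: full
enumeration, minimizing expected whole-vial mg; the greedy solution matches
it on the default cohort.

The minimal-cost designed table at 1.25 mg/kg
([60, 70, 70, 80, 100, 110] mg on the default cohort) is close to but not
identical with the packaged table ([50, 60, 70, 80, 90, 100] mg): the
packaged table favors round 10-mg steps and a lower heavy-band dose, and its
lightest/heaviest band choices sit slightly outside the strict per-band
window the designer enforces.  The packaged table is therefore shipped as
data and evaluated (it passes all population-level equivalence gates), while
the designer documents what the constraints alone would produce.

## Costs (`evband.costs_report`)

Vials cost EUR 698 (20 mg) and EUR 1,047 (30 mg) — a uniform EUR 34.90/mg, so
mg-based and vial-based costing coincide; `treatment_cost` refuses mg-based
costing if a formulary ever breaks that uniformity.  Per-course cost =
average mg per administration × administrations × EUR/mg, with 15
administrations for monotherapy (5 cycles × 3) and 24 for combination
(12 cycles × 2).  Savings = 100 × (1 − alternative/reference).  All
arithmetic is full precision; rounding happens only at presentation.  The
headline number is the unweighted average of the four per-level monotherapy
savings percentages under whole-vial reference accounting, ≈ 17% on the
default cohort (per-level ≈ 15–20%, larger at lower dose levels where the
vial grid is coarser relative to the dose).

## What the synthetic cohort does and does not represent

The cohort reproduces calibrated population summaries of exposure and drug
use; it does not reproduce any real trial population's demographics,
covariate correlations (e.g. weight–sex–clearance beyond allometry), renal or
hepatic function effects, time-varying clearance, or treatment
discontinuation.  Cost projections use fixed median treatment durations and
Dutch list prices, exclude pembrolizumab and administration costs, and make
no cost-effectiveness claims.
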