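# Methods

## The problem

The euglycemic hyperinsulinemic clamp is the reference measurement of
whole-body insulin sensitivity, but it is invasive and impractical at
epidemiological scale, so fasting surrogate indices — HOMA-IR, FIRI,
QUICKI, the glucose/insulin ratio — and non-laboratory adiposity measures
(BMI, waist circumference, waist-to-height ratio) are used instead.
`clampval` implements, as a reusable and tested pipeline, the validation
of those surrogates against clamp-derived insulin sensitivity in a cohort
of non-diabetic adults: robust correlations, dependent-correlation
comparisons, robust multiple regression, and tertile classification
agreement.  Because no subject-level data are distributed with the study
this package models, a seeded synthetic-cohort generator reproduces the
statistical structure the analysis assumes, and every stage is validated
against that generator.

## Clamp M value

During the clamp, insulin is infused at 80 mU/m² body surface area per
minute and 20% glucose at a variable rate holding blood glucose at
100 mg/dL, with 5-minute glucose measurements over 0–100 min and plasma
insulin sampled fasting and at 80/90/100 min.  Insulin-mediated glucose
uptake is

&nbsp;&nbsp;&nbsp;&nbsp;M = (mean GIR over 80–100 min) × (group-mean steady-state glucose / individual steady-state glucose) / (kg fat-free mass)

in mg·min⁻¹·kg⁻¹ FFM; an unadjusted variant divides by total body weight
instead.  Window endpoints are inclusive; nominal insulin sample times
are matched to the grid within ±0.5 min; a within-window glucose CV ≥ 5%
is flagged with a warning but the subject is retained (the protocol
reports a mean CV, not a per-subject exclusion).  The group-mean
steady-state glucose is computed over the complete-case analysis set
before per-subject M values.  A division of M by steady-state insulin is
dimensionally incompatible with M in mg/min/kg at the magnitudes the
method reports, so the insulin-normalised quantity is exposed only as the
auxiliary output `m_per_insulin` (M/I), never as the headline M.

## Fasting indices

HOMA-IR = G₀·I₀/22.5 and FIRI = G₀·I₀/25 with glucose in mmol/L and
insulin in µU/mL (so FIRI ≡ 0.9·HOMA-IR exactly); QUICKI =
1/(log₁₀ I₀ + log₁₀ G₀) with glucose in mg/dL; glucose/insulin ratio in
mg/dL per µU/mL.  QUICKI's log base and the ratio's glucose unit are
configurable because unit conventions vary across the clinical
literature.  LDL cholesterol is computed by Friedewald's formula
LDL = TC − HDL − TG/5 (mg/dL), valid for TG ≤ 400 mg/dL (enforced as an
error); being linear, the formula applied to group-mean lipids equals the
group mean of per-subject LDL, which is what makes published group-mean
LDL values reproducible from published TC/HDL/TG means.  The
mmol/L↔mg/dL glucose factor is fixed at 18.016.

## Robust correlation machinery

Associations with clamp M are estimated on Box-Cox shaped scales: for
each variable, λ is the grid argmax (λ ∈ [−3, 3], step 0.01) of the
normal-model profile log-likelihood with the Jacobian term, with natural
log at |λ| < 10⁻⁸.  The correlation itself comes from an EM fit of a
multivariate t distribution with fixed degrees of freedom (default
df = 4, a common robust-estimation choice; configurable): E-step weights
wᵢ = (df + p)/(df + dᵢ²) with dᵢ² the Mahalanobis distance under the
current location/scatter, M-step the weighted mean and weighted scatter
normalised by n, iterated until the largest parameter change is below
10⁻⁸.  As df → ∞ the estimate converges to the sample covariance, which
is tested against Pearson at df = 10⁶.  Confidence intervals use the
Fisher z transform: tanh(atanh r ± z_{α/2}/√(n−3)); this convention
reproduces the study's printed intervals at n = 79 (to within one unit
in the last printed digit, attributable to the printed r being rounded
to 2 dp).

Two correlations sharing the clamp variable are compared with the
Williams-modified Steiger t (the single-shared-variable form), df = n−3.
Because resistance indices correlate negatively and sensitivity indices
positively with clamp M, predictive strength is compared on |r|: signs
are aligned before applying the test.  The HOMA-IR vs FIRI comparison is
skipped as degenerate — the two are exact monotone transforms of each
other, so their correlations with any third variable are identical by
construction and the three-variable scatter matrix is singular.

## Robust regression

Clamp M is regressed on each index plus sex (female = 1) and waist
circumference (and on adiposity-only models: sex + one of BMI, waist,
WHtR, or BMI + waist) by Huber M-estimation: IRLS with ψ truncated at
1.345 robust-scale units (95% Gaussian efficiency) and scale
re-estimated by normalised MAD each iteration, delegated to statsmodels'
RLM.  Variables enter on their Box-Cox scales by default (raw scale is
an option).  R² for a robust fit is defined as the squared Pearson
correlation of fitted versus observed values — stated in all outputs,
since no single R² convention exists for M-estimators.  Coefficient
magnitudes therefore depend on the transform scaling and are not
comparable across datasets; the analysis reads them for sign,
significance and R².

## Tertile agreement

Thirds of insulin sensitivity are rank-based with a stable tie rule, so
they are invariant to strictly monotone transforms (hence HOMA-IR and
FIRI rows are always identical).  Directions are fixed so "high" always
means high sensitivity: increasing thirds of clamp M, QUICKI and
glucose/insulin ratio; decreasing thirds of age, BMI, waist, WHtR,
fasting insulin, HOMA-IR and FIRI.  Group sizes are floor(n/3) with
remainders assigned to the high then the medium third — the convention
that reproduces the published margins (47 → 15/16/16, 32 → 10/11/11).
Thirds are formed within sex and pooled for the all-subjects stratum
(pooled margins 25/27/27 at n = 79).  Agreement is summarised by the
3×3 cross-table, per-reference-category % correct, overall agreement and
unweighted Cohen's κ; κ confidence intervals are percentile bootstrap
(default B = 1000), resampling subjects with replacement — stratified by
sex wherever the thirds themselves are sex-specific — and recomputing
tertiles and κ per replicate.  Replicates with degenerate margins are
skipped with a warning.

## Descriptive tables

Strata are sex × BMI category (lean < 25, overweight 25–29.9, obese
≥ 30 kg/m²; half-open bins).  Within sex, variables are compared across
categories by Kruskal-Wallis (tie-corrected, χ² reference) and by a
linear-trend test implemented as the two-sided t-test of the
least-squares slope on ordinal scores 0/1/2 (the output states this
definition).  Sex-by-category heterogeneity is the 1-df t-test of the
sex × ordinal-score product term in a linear model with main effects; a
2-df categorical-interaction F-test is available as an option.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuned.
Per-stratum means and SDs for age, BMI, percent fat, waist, hip, blood
pressure, lipids and fasting glucose are bundled in a versioned JSON
config (`clampval/data/cohort_defaults.json`) mirroring the modelled
cohort: n = 87, 51 men, stratum sizes 23/18/10 (men) and 14/9/13
(women).  Each subject has a latent trivariate standard normal
(Z_S, Z_A, Z_H):

* **Z_S → S_true**, log-normal calibrated to the clamp M distribution
  (mean 10.5, SD 3.2 mg/min/kg FFM);
* **Z_A** is a single adiposity factor: its quantile selects the BMI
  category at the configured stratum proportions, and its
  within-category position shifts BMI, waist, hip and percent fat
  (within-stratum loading 0.5);
* **Z_H → log HOMA-IR**, log-normal calibrated to the pooled HOMA
  distribution (mean 1.36, SD 0.85); fasting insulin is derived as
  HOMA × 22.5 / G₀ with G₀ drawn per stratum, truncated below the
  diabetic threshold of 7 mmol/L.

Default latent correlations: corr(log S, log HOMA) = −0.30,
corr(log S, adiposity) = −0.45, corr(adiposity, log HOMA) = +0.45,
chosen to reproduce the observed association pattern (fasting indices
r ≈ ±0.3, adiposity r ≈ −0.4 with clamp M).  The log-HOMA correlation is
the primitive rather than log-insulin because the end-to-end recovery
experiment (does the pipeline's HOMA-vs-M correlation reproduce the
configured value?) is only well-posed that way; independent glucose
variation attenuates the implied log-insulin correlation by a factor of
about 0.98.  BMI/waist/WHtR share one adiposity factor rather than
having separate target correlations because they are near-collinear in
real cohorts.

Clamp traces impose the steady state rather than solving
glucose-insulin kinetics: blood glucose ramps from the fasting level
onto the 100 mg/dL target, reaching it exactly by 40 min, and GIR ramps
onto S_true × FFM; both carry multiplicative Gaussian noise (glycemic
CV 2%, GIR CV 3% per sample, insulin CV 3% by default).  Steady-state
insulin is fasting insulin plus 1.9 × infusion rate × BSA/1.73 µU/mL
with Du Bois body surface area — an effective inverse clearance giving
realistic steady-state levels (~150–180 µU/mL) at the 80 mU/m²/min dose.
With all noise at zero the M computation recovers S_true exactly
(machine precision), which closes the loop on the clamp arithmetic.

**What the generator does not emulate:** measurement error in
anthropometry and assays beyond the clamp noise; the dual body-composition
instrumentation of real studies; non-Gaussian tails, assay floors, or
day-to-day biological variation in fasting values; any dynamic
glucose-insulin physiology (no minimal-model kinetics, no hepatic
glucose production).  Passing tests therefore demonstrate the
correctness and calibration of the *statistical machinery* under the
assumed structure, not the field performance of the indices in real
populations.

## Numerical choices and degenerate inputs

Box-Cox requires strictly positive inputs; variables that can touch zero
are shifted minimally above zero before λ selection (a monotone shift,
preserving ranks).  Constant vectors are rejected for λ selection,
correlation and R².  The t-EM raises on singular scatter or
non-convergence (500 iterations); tertile ties straddling a cut are
resolved by stable original-order ranking with a warning; bootstrap
replicates with degenerate κ margins are skipped and counted.  All
randomness flows from user-supplied integer seeds through
`numpy.random.Generator`; identical configuration and seed give
byte-identical report bundles.

## Problem sizes used in the test and acceptance suites

Marginal-fidelity checks use cohorts of 4000–5000 subjects; the
end-to-end correlation-recovery experiment uses n = 5000 (Monte-Carlo SE
≈ 0.011 for r ≈ 0.5, against a ±0.03 acceptance band); Monte-Carlo size
checks of the Steiger test use 2000 replicates at n = 79; bootstrap
coverage uses 300 outer replicates of n = 60 with B = 200.  These sizes
keep each suite run in tens of seconds while leaving the Monte-Carlo
error small relative to every asserted tolerance.

## Known limitations

* The complete-case convention (no imputation) matches the modelled
  study but discards information when missingness is informative.
* The robust-R² convention makes R² non-decreasing under added
  predictors only approximately for robust fits.
* The Box-Cox λ is chosen per variable marginally, not jointly for the
  pair being correlated.
* Bootstrap κ intervals are percentile intervals; no BCa correction.
* The generator's stratum-conditional construction reproduces stratum
  means/SDs approximately near category boundaries (truncation shifts
  realized-category means slightly).
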