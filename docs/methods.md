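# Methods

## The score

The YDR CHD score is a multiplicative relative-risk index. Each risk factor
contributes the consensus relative risk of the subject's own level to the
numerator; the denominator is the product, over the same factors, of the
factor's prevalence-weighted mean RR in the reference population
(Σₖ Pₖ·RRₖ, the reference level contributing (1 − Σ exposed)·1.0). The
printed form of the equation shows binary factors; the Σₖ Pₖ·RRₖ term is its
direct multi-level generalisation (smoking has 8 levels, cholesterol 5,
BMI 3) and reduces to P·RR + (1−P) for two levels. The ratio is the
subject's 10-year CHD risk relative to an average person of the same age
and sex: by construction a population drawn at the reference prevalences
averages to 1.

Applicability rules make the factor set profile-dependent:

* adiposity is **BMI for age < 60** and **waist circumference for age ≥ 60**
  (exactly one of the pair contributes, to both numerator and denominator);
* **secondhand smoke** applies only to subjects who are not current smokers
  (level ids beginning `current` mark current smokers). For a current
  smoker the factor contributes nothing to either side of the ratio — a
  model rule, not missing data.

Categories use the seven intervals with **inclusive upper bounds**
(… 0.9 < RR ≤ 1.1 is *about average*; RR ≤ 0.2 and RR > 5.1 are the
extremes). RR = 1.1 is therefore *about average* and RR = 5.1 *much above
average*. Scores are not capped; protective factors (multivitamin 0.80,
physical activity 0.55, several dietary factors) are handled identically to
harmful ones. Products are evaluated in double precision — with ≤ 18
factors and per-level RRs in [0.55, 7] there is no over/underflow risk and
no need for log-space accumulation.

Missing levels for an applicable factor raise an error by default, because
the validation cohort excluded such subjects; `impute_reference=True` opts
into treating them as the reference level. The consensus RRs nominally
describe lifetime risk while the score is read as a 10-year relative risk;
the equation is implemented at face value with no horizon adjustment.

## Parameters

Parameters live in a CSV, not code
(`factor_id,level_id,is_reference,consensus_rr,us_prevalence,nhs_prevalence,applicability`
plus the optional observed-RR columns `nhs_unadjusted_rr,nhs_multivariate_rr`),
so the cohort-observed prevalences or effect estimates can be swapped in for
sensitivity analyses. Prevalences are stored as printed percentages; the
loader converts to proportions and **recomputes the reference prevalence as
1 − Σ(exposed)** so that each factor's prevalences sum to exactly 1
(published percentage rounding would otherwise leave factors summing to,
e.g., 100.1%); the printed reference value is cross-checked within half a
percentage point. The packaged default encodes 18 factors (the adiposity
pair counted as two age-gated factors) with 46 levels.

## Synthetic cohorts

The generator emulates the structure — not the microdata — of the score's
published validation cohort: by default 55,802 women, integer ages uniform
on 47–74, factor levels drawn independently per factor at the cohort's
observed prevalences, and a Bernoulli 10-year CHD outcome with

    risk = baseline × Π effect-RR(level) × a^(age − 60),   clamped to ≤ 1

*Risk-scale multiplication.* Effects multiply the risk, matching the
equation's risk-ratio semantics, not the odds; at ~2% incidence the
distinction is immaterial, which is why the logistic (odds-scale) estimators
downstream still recover the generating effects. Clamping at 1 affects only
profiles with extreme joint exposure (order 10⁻⁴ of subjects at default
settings); clamp counts are logged and stored in `attrs`.

*Age effect.* `age_effect_or_per_year` defaults to **1.10 per year**,
chosen so that the incidence gradient across the 5-year age bands spans
roughly a factor of five between the youngest and oldest bands, matching
the published case counts' gradient; it is a configuration knob, not an
estimate. Age 60 is the anchor (`age_reference`).

*Baseline calibration.* `calibrate_baseline` equates the analytic expected
marginal incidence — the mean over ages of the age effect times the product
of per-factor mean effect RRs, with the smoking × secondhand pair treated
jointly and the adiposity pair through its age gates — to the target
(default 2.1%). The identity is linear in the baseline, so the solution is
closed-form; the clamp is ignored analytically and verified negligible by a
10⁶-draw Monte-Carlo oracle in the tests.

*Age confounding hook.* Optionally, the exposed prevalences of current
smoking and elevated BMI scale linearly with age (×(1+s) at the youngest
age, ×(1−s) at the oldest; reference levels absorb the shift). This makes
the top score categories younger, so their crude odds ratios are pulled
toward 1 relative to age-adjusted ones — the qualitative confounding
pattern observed in the real validation (top-category OR 1.71 crude vs 2.48
age-adjusted). The strength s is a knob; 0.5 is used in examples and tests.

*Seeding.* One master seed; per-stage child streams (ages, each factor,
outcome) are spawned deterministically, so identical specs give identical
tables byte-for-byte.

What the generator does **not** emulate: joint factor distributions (no
published joint distribution exists; factors are independent given age
except through the explicit hooks), questionnaire instruments and follow-up
cycles, non-uniform age distributions (configurable range, uniform shape),
and case ascertainment. Passing validation on synthetic cohorts therefore
demonstrates the estimators' correctness under the stated generating
process, not the tool's real-world calibration.

## Validation statistics

*Category odds ratios.* For a logistic model containing only category
indicators, the MLE odds ratios equal the empirical cell odds ratios, so
the closed-form routine (Wald CI from the four reciprocal cell counts) is
both the fast path for published count tables and an independent oracle for
the regression route, which must agree to 1e-6 relative. Zero cells yield
flagged infinite/zero bounds, with no continuity correction. Age-adjusted
ORs add age as a continuous covariate; age-stratified tables refit within
stratum rather than using interaction terms. The published tables label
these "RR"; at 2% incidence OR ≈ RR, but they are odds ratios and are named
as such here.

*Per-factor models.* Each factor's non-reference levels enter as
indicators, fit alone (among the subjects the factor applies to) and
jointly. In the joint model the age-gated BMI and waist indicators are zero
outside their stratum and share the pooled reference, and secondhand smoke
is coded 0 for current smokers — a coding this package chose; the original
analysis's recoding rules are not public. Note a structural caveat: because
the adiposity dummies identify the age stratum, any age→outcome gradient
loads onto them when age is omitted; recovery checks against a simulation
with an age effect therefore use the `adjust_age=True` variant, which
matches the generating process. The default (no age term) mirrors the
published factor table.

*Concordance.* The c-statistic is the tie-corrected Mann–Whitney
probability that a random case outscores a random non-case, computed from
midranks (so it is invariant under strictly monotone transforms and equals
the trapezoidal ROC area). For the category model the fitted risks are the
category event rates, so c reduces to a sum over category pairs computable
from a count table alone — used both on published counts and as an oracle
for the pairwise route (agreement to 1e-12, and to an O(n²) pair
enumeration at n ≤ 500). CIs use the **Hanley–McNeil** variance by default
— the published analysis cites a CI method without formulas, so the method
is stated in every output — with **DeLong** available as an option. The
age-adjusted c-statistic is the concordance of the fitted probabilities of
the age-plus-categories logistic model (an interpretation; the original's
exact construction is unspecified). Strata are compared with
z = (c_A − c_B)/√(var_A + var_B) against a normal reference, an
independent-samples approximation (the cited comparison method's exact
variance estimator is not reproduced in the source); its p-values are
labelled approximate.

*Report.* `build_report` assembles incidence, per-stratum category tables
(counts, crude, age-adjusted), c-statistics (overall, age-adjusted, the
five age bands ≤55, 56–60, 61–65, 66–70, >70) and the per-factor table;
every number traces to one of the operations above. On tiny or degenerate
cohorts fragile fits degrade to recorded flags rather than exceptions.

## Problem sizes and numerical choices

Simulation-based tests use cohorts of 50,000–100,000 subjects (10⁶ for the
calibration oracle), sizes at which every Monte-Carlo tolerance (3 standard
errors) has comfortable resolution while the full suite stays fast.
Comparisons against published two-decimal values use ±0.005 on unrounded
computed values. Two printed cells of the published age-stratified tables
(1.78 and 0.74) disagree at the last digit with the odds ratios implied by
their own printed counts (1.77, 0.73); the table-diffing command therefore
reports agreement within one unit of the printed last digit, while all
headline values are reproduced at ±0.005.

## Known limitations

* The full-model denominator has no published reference value; it is
  pinned by an independent spreadsheet-style oracle over the parameter
  table, not by an external number.
* Whether the deployed web tool caps extreme scores is unknown; no cap is
  applied.
* The age-adjusted odds ratios and c-statistics of the original validation
  require the original subject-level cohort and are reproduced here only
  qualitatively (direction and mechanism) on synthetic data.
* Exclusion filtering implements the published thresholds (prior heart
  disease; ≥10 missed diet items; <500 or >3500 kcal/day, bounds retained;
  any missing applicable factor) but the auxiliary columns are synthetic
  constructs in all shipped data.
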