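# Methods

## Scope and design

`famagg` estimates familial aggregation of a binary, register-coded
diagnosis (unspecified syncope, R55.9, used as a proxy for reflex syncope)
across relative pairs of graded genetic resemblance.  It is a *descriptive*
familial-association toolkit: it stops at rates, odds ratios, tetrachoric
correlations, survival contrasts and a resemblance interaction test.  It
deliberately does **not** fit variance-component (ACE) models, frailty
models or Cox regressions, and it performs no consanguinity or
ICD-validation logic.

## Follow-up model

Follow-up is resolved at whole-year granularity, matching register data that
report years only.  For each person,

- start = max(birth year, study start; default 1997),
- end = min(first syncope event, death, emigration, study end; default 2015),
- person-years = end − start, with a floor of 0.5 person-years when the
  first event falls in the opening year, so no observed event carries zero
  exposure.

A person whose window closes before it opens (death/emigration before the
study start, or a prevalent event before start) is flagged *excluded* and
contributes neither events nor person-time; this mirrors the cohort
exclusion rules rather than raising an error.  Exposure to a relative's
history is classified at **baseline** (ever-affected relative during the
study window).  A time-dependent classification, in which exposure begins at
the relative's event year, is a recognised alternative; the baseline
convention was chosen because the person-level "persons at risk" layout of
familial-risk tables reads most naturally as a fixed attribute, and the
package keeps the pair-row event years so a time-dependent variant can be
built on top.

## Relative pairs and double entry

Pairs are extracted from parent links: twins share a twin-group id (a
same-parents + same-birth-year fallback exists but is opt-in, because
year-resolution data cannot distinguish twins from same-year singleton
siblings); full siblings share both parents (twin pairs removed);
half-siblings share exactly one parent; first cousins have parents who are
full siblings and share no parent themselves.  Both parents must be known.
A sibship of three yields six ordered rows: the design is pairwise, not
set-based, and every dataset is double-entered, so each person's outcome is
regressed on each relative's status.  A person may appear in several
relationship datasets.

Cohort rules (all configurable): children born 1948–2005 to parents born
1932–1985; born in the country, with parents born in the country; no
emigration before age 17; and no member of the natal nuclear family (both
parents plus the children of that couple) dead or emigrated before the study
start.  Whether the "family lost before study start" rule should reach
beyond the nuclear family is genuinely open; the nuclear scope is the
default and a `family_scope="members"` switch restricts it to the pair
members themselves.

## Estimators

**Incidence rates** are cases per 1000 person-years with exact Poisson
(chi-square/gamma) 95% intervals; the IRR uses the log-normal interval with
Var(log IRR) = 1/cases₁ + 1/cases₀.

**Crude ORs** are person-level (cases and non-cases among exposed vs
unexposed persons) with the Woolf interval.  A zero cell receives the
Haldane–Anscombe 0.5 correction and is flagged.

**Adjusted ORs** are logistic regressions on double-entered pair rows:
outcome = index person's flag, exposure = relative's flag, covariates (birth
year, sex, county dummies, education > 11 years) belong to the index person.
Covariates that are constant in a subset (e.g. sex in a single-sex stratum)
are dropped rather than left to break the fit; separation or
non-convergence raises an explicit fit error.  Standard errors are reported
as fitted, **without** a clustering correction for double entry — the
double- vs single-entry sensitivity below quantifies exactly what that
omission costs; a cluster-robust (unordered-pair cluster) option exists but
is off by default.

**Tetrachoric correlation** assumes the two binary outcomes dichotomise a
latent bivariate normal.  Thresholds are fixed at the probits of the
observed margins (two-step ML); with empirical margins the ML estimate of ρ
solves P(X>τ₁, Y>τ₂; ρ) = n₁₁/n, found by bracketed root-finding.  The
bivariate normal CDF is evaluated in closed form via Owen's T function, so
the estimate is deterministic; the SE comes from the numerical second
derivative of the profile log-likelihood.  Perfect association is clamped
to ±(1−10⁻⁶) with a warning; a degenerate margin raises.  The estimator is
cross-checked in the tests against an independent ρ-grid maximiser whose
orthant probabilities come from one-dimensional quadrature.

**Interaction test.**  All relationship datasets are pooled; each row
carries its genetic resemblance (0.66 twins as an MZ/DZ-mixture mean, 0.5
full siblings, 0.25 half-siblings, 0.125 cousins).  The logistic model adds
resemblance and resemblance × relative-affected terms; the reported quantity
is the interaction OR per unit resemblance with its Wald CI and p-value.
Resemblance enters continuously by default; a categorical
(relationship-dummy) main-effect variant is available because the coding
choice is not canonical.

**Single vs double entry.**  Single entry keeps the orientation whose index
id sorts first.  For the tetrachoric the unordered-pair table is defined as
every double-entry cell halved (the orientation of a discordant unordered
pair is arbitrary, so the discordant mass is split evenly); this makes the
point estimate exactly entry-invariant while doubling its variance, which
is also how the Monte-Carlo error of recovery tests is computed (fitted SE
× √2).  Person-level measures (rates, crude OR) are entry-invariant by
construction.

**Survival.**  Kaplan–Meier curves use time since each person's follow-up
start with right censoring at death/emigration/study end; groups are the
baseline relative-history classes; the two-group log-rank statistic is χ²
with 1 df.  At tied year-resolution times events precede censorings.

## The synthetic registry

The generator emits three-generation extended families: a grandparent
couple, two full-sibling parents with founder spouses, their children
(sibships of two or three; a configurable fraction are twin births with
latent MZ/DZ zygosity), optional re-partnering producing half-siblings, and
cousins across the two sibships.  Liability is L = A + C + E with
Var(A) = h², Var(C) = c², Var(E) = 1 − h² − c².  A is propagated as
child = mid-parent + Mendelian noise (variance h²/2), so Corr(A_i, A_j)
equals the pair's genetic resemblance without any per-pair bookkeeping; MZ
co-twins share A exactly.  C is drawn per rearing household and shared by
full siblings and twins of the same couple (half-siblings and cousins do
not share C; the grandparent household gives the two linking parents their
shared C).  The diagnosis threshold is found by root-finding so the
sex-averaged P(L + s·female > τ) equals the target prevalence; the female
liability shift s produces the observed female excess.

Default study conditions (chosen once, from the published cohort's printed
characteristics, and not revisited): prevalence 0.023; h² = 0.20 and
c² = 0.01, the values implied by the printed tetrachoric ladder
(0.5·h² + c² ≈ 0.11 siblings, 0.25·h² ≈ 0.05 half-siblings); female shift
0.22 liability units (probit arithmetic from female ≈ 2.9% vs male ≈ 1.7%);
MZ fraction 0.31 of twin pairs, which reproduces the ≈0.66 Weinberg mean —
the MZ/DZ mix is a modelling choice, not a register fact; differential
(non-reflex) transient-loss-of-consciousness codes on 2.07% of cases;
onset age log-normal with median 22 and σ = 0.54 (quartiles ≈ 17/34),
truncated to each person's follow-up window.  Because of that truncation
the *observed* onset ages in the simulated analysis cohort run a few years
younger (median ≈ 18) than the latent law — the cohort is young, so late
onsets are right-truncated; the same mechanism operates in real register
data.  Death and emigration are drawn at small constant hazards purely to
exercise censoring and the exclusion rules.

What the generator does **not** emulate: realistic fertility/mortality
schedules, assortative mating, dominance variance, diagnosis-seeking
behaviour, code misclassification, or migration waves.  Passing recovery
tests therefore demonstrates estimator correctness under the liability
model, not robustness to those real-data features.

All draws come from one seeded generator in a fixed documented order, so a
(params, seed) pair reproduces the registry byte for byte.  A direct
logistic pair-row generator (`simulate_association_rows`) plants known
exposure log-odds — optionally sex-pair-specific — for regression
parameter-recovery tests, which is cleaner than overloading the registry
simulator with a sex-specific familial-effect knob.

## Numerical and test-design choices

- Tetrachoric root-finding brackets ρ in ±(1−10⁻⁶) with xtol 10⁻¹²;
  the SE uses a central second difference with step 10⁻⁴.
- Validation problem sizes were chosen as the smallest that make the
  checks sharp: ~460k simulated persons (42 000 extended families, twin
  sibship probability 0.30, re-partnering 0.30) give ≥50 000 double-entered
  rows per relationship class for tetrachoric recovery within 3 Monte-Carlo
  SEs; interaction power uses 20 replicates of ~200k pooled rows under
  h² = 0.3 (Monte-Carlo power ≈ 95%, so the ≥80% criterion has headroom)
  and 10 null replicates under h² = 0.
- Under the null the pooled interaction test is mildly anti-conservative
  (empirical rejection ≈ 13% at nominal 5%) because double-entered rows are
  not independent; this is inherent to the unclustered design choice above
  and is why the null check bounds the rejection rate rather than pinning
  it at 5%.
- Rounding for display: two decimals for rates, ORs and correlations.
- Printed-table check values: the published unexposed incidence rates are
  not all exactly reproducible from the printed cases and person-years
  (e.g. 254/191 532 → 1.33 vs a printed 1.34), and the cousin
  persons-at-risk figures are internally inconsistent with the overall
  prevalence; the package reports full-precision rates and the test suite
  anchors only on the internally consistent cells (the exposed-stratum
  rates and the twin/sibling crude ORs).

## Known limitations

Year-granular time makes all within-year ordering conventional; the
baseline exposure classification ignores when the relative's event
happened; double-entry SEs are knowingly naive (quantified, not corrected,
by default); the twin resemblance 0.66 is a mixture mean, so twin-set
estimates conflate MZ and DZ aggregation unless the latent zygosity is
available (in simulations it is, via the truth table).
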