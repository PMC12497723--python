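# Methods

This note documents the statistical model behind each stage, the default
parameters and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices that affect results.

## Report model and deduplication

A spontaneous reporting database is a set of case reports.  Each report
carries demographics (sex, age, weight, country, reporter occupation,
outcome codes, receipt date FDA_DT, event date EVENT_DT), one or more
drug records with role codes (PS primary suspect, SS secondary suspect,
C concomitant, I interacting), a set of reaction PTs, and optional
therapy dates and indications.  Reports arrive in versions: the same
CASEID may appear under several PRIMARYIDs as follow-ups supersede the
original.  Deduplication keeps, per CASEID, the row with the most recent
FDA_DT, breaking ties by the higher PRIMARYID (numeric comparison when
both ids are numeric strings, else lexicographic).  Partial dates (4- or
6-digit) are ordered by zero-padding to 8 digits, which implements
"most recent on best available precision"; a month-precision date sorts
just below the first day of that month.

The exposed cohort is the set of deduplicated reports carrying the
target drug with role PS; everything else is background.  Drug names are
matched after normalization (trim, uppercase, whitespace collapse,
trailing-dosage stripping) with an optional user synonym table as the
extension point for brand names — the matching rule used upstream of any
given extract is rarely documented, so exact normalized match is the
default.

## Contingency tables

For a term *t* at PT or SOC level, the four cells are counted at case
level: a case contributes at most once to *a* (exposed, reports *t*) even
if the PT appears on several reaction rows, and at most once to a SOC
even when several of its PTs map there.  The background is the whole
non-exposed database, the standard FAERS-wide comparator.  PTs missing
from a user-supplied SOC map are pooled into an `UNMAPPED` class and
logged.  Screens cover every term with *a* ≥ 1.

## Disproportionality statistics

**ROR** = *ad/bc* with the Wald CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
**PRR** = [a/(a+b)]/[c/(c+d)], companioned by the Yates-corrected χ² of
the 2×2 table.  When any cell is zero, the Haldane–Anscombe +0.5
correction is applied to all four cells for ROR and PRR only; nonzero
tables are never corrected, so typical estimates are unbiased by the
continuity device.  A degenerate margin yields χ² = 0.

**BCPNN.** The information component is modelled with the closed-form
posterior moments of Bate et al. (1998): with priors
α₁ = β₁ = γ₁₁ = 1, α = β = 2 and γ chosen so the prior IC expectation is
0, E(IC) = log₂[(a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁))] and V(IC)
is the matching delta-method variance.  IC025 = E(IC) − m·√V(IC) with
multiplier m = 2 by default.  Published FAERS analyses are not always
explicit about their BCPNN variant; the prior and the multiplier are
therefore configuration options rather than constants.  The prior-free
point estimate log₂(aN/((a+b)(a+c))) is exposed separately
(`ic_point`) and is exactly 0 under independence.

**MGPS.** The reporting ratio λ of each drug–event pair is given a
two-component gamma mixture prior p·Γ(α₁,β₁) + (1−p)·Γ(α₂,β₂) (rate
parameterisation).  Given the independence-expected count
E = (a+b)(a+c)/N, the marginal of *a* is a mixture of negative
binomials; the prior is fitted once per screen by maximizing that
marginal likelihood over all tables.  Optimization runs L-BFGS-B in
(log α₁, log β₁, log α₂, log β₂, logit p) from DuMouchel's canonical
start (0.2, 0.1, 2, 4, 1/3), a start derived from a single-gamma fit
(protecting the nested no-mixture case), and three seeded random
perturbations, followed by a Nelder-Mead polish; components are
returned in canonical order (smaller prior mean first), making the fit
deterministic and label-stable.  The posterior of λ is again a
two-gamma mixture in closed form; EBGM = exp(E[ln λ]) and EBGM05 is the
posterior 5th percentile found by bracketed root-finding on the mixture
CDF.  A no-shrinkage comparator (`ebgm_simplified`: a/E with an exact
Poisson-rate chi-square lower bound) is provided for diagnostics.

**Thresholds.**  Defaults follow the common screening convention: ROR —
a ≥ 3 and CI lower bound > 1; PRR — a ≥ 3, PRR ≥ 2, χ² ≥ 4; BCPNN —
IC025 > 0; MGPS — EBGM05 > 2.  All are configurable; boundary values do
not flag.  Consensus "any" (≥ 1 method) and "all" (all four) are both
always reported; "all" is a subset of "any" by construction.  No
multiple-testing adjustment is applied, matching standard
disproportionality practice.  Rankings sort by case count descending
with ties broken by ROR descending then term, so outputs are
deterministic.

## Time to onset

Onset is the day difference between the PS drug's therapy start and the
case's event date; both must be day-precision, otherwise the case is
excluded as missing (and counted).  Negative differences are excluded
and counted separately.  Same-day onsets map to 0.5 days rather than
being dropped: zero is outside the Weibull support, but same-day events
are informative early-failure evidence.  Quartiles use linear
interpolation (type 7), stated here because the median/IQR are reported
quantities.  Binning uses (0–30], (30–60], (60–90], (90–180],
(180–360], >360 days, upper bounds inclusive.

The two-parameter Weibull (scale α, shape β) is fitted by maximum
likelihood: β solves the one-dimensional profile-likelihood equation by
bracketed root-finding (bracket grown geometrically from (10⁻³, 1]), α
then follows in closed form, so the fit has no stochastic element.  95%
CIs are Wald intervals on (log α, log β) using the observed Fisher
information evaluated by central finite differences (step 10⁻⁴);
log-scale intervals respect positivity.  Classification: *early
failure* if the β CI lies below 1, *wear-out* if above 1, *random*
otherwise.  Censoring is not modelled — spontaneous reports are events
by construction.

## Subgroup and sensitivity analyses

The sex-stratified screen analyses each stratum's exposed cases against
the same-stratum background, which removes the stratifier as a
confounder; strata with fewer than 10 exposed cases (configurable) are
skipped with a log entry.  "Not specified" sex forms its own stratum
but is conventionally not reported as a signal stratum.  The
monotherapy filter keeps exposed cases whose single drug record is the
target with role PS; the background is untouched.

## Synthetic generator

The generator emulates the data model the pipeline consumes, with every
estimand planted:

* ~200 PTs with baseline probabilities geometric from 0.03 down to
  5·10⁻⁴ (a skewed frequency spectrum, as in real term distributions);
  each case draws each PT independently and is guaranteed ≥ 1 PT.
* Planted signals multiply a PT's baseline by a chosen rate ratio in
  exposed cases (clipped at probability 1, with the clipped effective
  ratio reported by `ground_truth`); a signal may be restricted to one
  sex for subgroup experiments.
* Defaults: 50,000 cases with exposure probability 0.05, giving an
  exposed cohort of ~2,500 — the size of a typical single-drug FAERS
  cohort — against a desk-scale background.  Demographic margins follow
  the published profile of cyclobenzaprine reports (53.8% female, 85.4%
  US, 27.7% consumer-reported, and so on).
* Onsets are Weibull (default shape 0.38, scale 46.9 days — a strongly
  front-loaded hazard) ceiled to whole days (minimum 1), since report
  dates have day precision; event date = therapy start + onset, receipt
  date = event + 0–60 days.  Only a fraction of reports
  (`p_onset_recorded`, default 0.12) carry usable dates, mirroring how
  sparse onset timing is in practice.
* Duplicates are "older shadow copies": a second DEMO row with the same
  CASEID, strictly older FDA_DT and lower PRIMARYID, plus copies of the
  drug/reaction rows — so the deduplication rule's correct answer is
  exact (`expected_retained_ids`).
* Each case has exactly one PS drug; co-medications (probability 0.6,
  1–3 extra records) always get role C and never the target drug, which
  makes the monotherapy filter's ground truth exact.

What it does **not** emulate: calendar-time reporting dynamics
(stimulated reporting, secular trends), correlated PT co-occurrence
(term draws are independent given exposure), drug-name noise, real
MedDRA structure (the bundled SOC mapping is a deterministic
round-robin assignment), or receipt dates bounded by an extraction
window (heavy-tailed onsets can push receipt dates past the nominal
period).  Passing tests therefore demonstrate correctness of the
estimators and the pipeline's plumbing under a faithful independence
model, not robustness to real-world reporting biases.

## Problem sizes and determinism

All stochastic tests run at fixed seeds.  Recovery experiments use
20,000–50,000 cases per replicate and 3–20 replicates; the Weibull
shape-recovery study uses 100 replicates of n = 281 — the published
onset-sample size — drawn as continuous Weibull variates.  Day-ceiled
onsets from the date pipeline inflate the fitted shape by roughly +0.07
at shape 0.38 (a discretisation bias: one fifth of the mass of this
distribution falls below one day and is rounded up), so rounding-free
draws are the right input for checking the MLE itself, and the date
pipeline's fit is asserted against a correspondingly wider band.  The
acceptance script reports the mean recovered shape over 100 replicates.
Goodness-of-fit of the generator's day-rounded onsets is checked at
integer support points, where P(⌈X⌉ ≤ k) = F(k) holds exactly.

## Known limitations

Disproportionality statistics measure reporting association, not
causation, and the unstratified background leaves confounding by
age/sex/era in place except where the subgroup module removes it.  The
BCPNN variant and threshold constants differ across published analyses;
both are configurable rather than canonical.  The MGPS mixture
likelihood is flat in some directions (notably when the data carry no
mixture structure), so fitted hyperparameters are less reproducible
than the EBGM values they induce, which are stable.  HLT/HLGT
intermediate MedDRA levels, covariate-stratified MGPS and MCMC BCPNN
are out of scope.
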