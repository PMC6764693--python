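# Methods

`deescbias` quantifies confounding by indication in observational studies of
antibiotic de-escalation in community-acquired pneumonia (CAP). The package
implements the full chain — spectrum ranking, course classification,
propensity estimation, time-dependent Cox regression, and a calibrated
simulation of an unmeasured "clinically stable at 72 h" confounder — plus a
synthetic cohort generator that stands in for individual-level trial data,
which are not publicly deposited.

## Spectrum ranking and course classification

Antibiotics carry a rank 1 (narrow spectrum: penicillin, amoxicillin,
tetracyclines), 2 (broad: first/second-generation cephalosporins,
co-amoxiclav, co-trimoxazole, clindamycin, macrolides) or 3
(extended/restricted: third/fourth-generation cephalosporins,
fluoroquinolones, aminoglycosides, piperacillin-tazobactam, carbapenems,
vancomycin). A combination regimen takes the *highest* component rank,
except that any beta-lactam plus any macrolide is rank 3 outright — against
respiratory pathogens that combination is broader than either drug. The
default table ships as an editable CSV (`data/rank_table.csv`) with a
synonym list; unknown drug names are hard errors, never silently defaulted.

A course is labelled by its **first rank-changing switch**: de-escalation
(lower rank), escalation (higher rank), or continuation (no change, or
equal-rank substitutions only). Equal-rank switches neither define the
label nor stop the search for a later rank change. After a de-escalation,
any later rise in rank is recorded; such patients keep the de-escalation
label but are censored at the later escalation in the survival analysis.
Stopping all antibiotics is not a rank event. Days are integer study days
with day 0 = admission; deaths on day 0 ("within 24 h") are excluded
upstream because those patients could never be de-escalated, as are
baseline ICU admissions and patients with no day-0 antibiotics. Patients
transferred to ICU after admission are not modelled; only the baseline ICU
flag is used.

## Survival model

Thirty-day mortality is analysed with Cox proportional-hazards regression on
counting-process (start-stop) data in which de-escalation is a
**time-dependent exposure**: unexposed person-time up to the switch day,
exposed from the switch day on. This avoids immortal-time bias — coding a
later-occurring exposure as present from baseline credits the exposed group
with the survival needed to reach the switch, and on null data demonstrably
drags the hazard ratio below 1 (shown in the test suite and the
interval-construction drivers). Escalated patients are censored at
escalation; everyone else at day 30.

Conventions, chosen where the analysis is otherwise under-determined:

- **Ties**: Efron approximation (day-granular data tie heavily; Efron is the
  accepted default).
- **Same-day events**: de-escalation precedes a same-day death (the patient
  dies exposed; the event interval gets length 0.5 so the engine accepts
  it), while death precedes a same-day escalation (the event is kept).
- **CIs**: Wald on the log scale.
- Rank-1 starters are excluded from the effect analysis (they cannot
  de-escalate).

The engine is lifelines' `CoxTimeVaryingFitter`; the test suite checks it
against an independently coded Efron partial likelihood maximised by grid
search, and checks that fixed-exposure start-stop data reproduce an ordinary
Cox fit.

### Proportional-hazards diagnostic

Over a 90-day horizon the exposure effect is allowed to differ across time
windows (default cuts at 10, 20, 30, 60, 90 days) by episode-splitting the
intervals and fitting exposure-by-window interactions; a likelihood-ratio
test against the constant-effect model is the global proportionality test.
A residual-smoother diagnostic was considered, but Schoenfeld residuals are
not available for start-stop data in the fitting library, and the piecewise
model answers the same question directly: on data simulated with protection
that vanishes after day 20 the early windows show the effect and the late
windows sit at the null, and under a constant effect the test rejects at
approximately the nominal 5% rate. Windows with no exposed events are
merged into a neighbour with a warning.

## Propensity score

The propensity for de-escalation is a maximum-likelihood logistic regression
on the baseline covariates: age, gender, smoking, diabetes, chronic
pulmonary disease, prior antibiotic use, empirical rank on day 1, season
(three dummies, winter reference), weekend admission, pathogen identified,
and the Pneumonia Severity Index components (nursing-home residence, the
comorbidity flags, altered mental status, vital signs, blood gas and
chemistry values, pleural effusion). Continuous covariates are standardised
internally, making the scores invariant to affine rescaling of the inputs.
The fitted score enters the Cox model as a single continuous covariate — no
matching, stratification or weighting. Discrimination is reported as the
AUC with DeLong's distribution-free confidence interval. Complete
separation aborts with advice to use the optional L2 (ridge) rescue, which
is logged when active.

## The calibrated unmeasured confounder

Clinical stability at 72 h is simulated as a single binary variable — the
static-confounder simplification; a time-varying stability trajectory is
deliberately out of scope. Its strength is governed by three parameters:

| parameter | default | meaning |
|---|---|---|
| overall prevalence π | 0.80 | share of the analysis set stable at day 3 |
| de-escalated-group prevalence π_de | swept 0.80 → 1.00 | stability among de-escalated |
| crude odds ratio with 30-day death | 0.14 | stability's outcome association |

Because the overall prevalence is a size-weighted average of the two group
prevalences, fixing π and π_de determines the continuation-group value
π_cont = (π·(n_de+n_cont) − π_de·n_de)/n_cont; values outside [0, 1] raise
an infeasibility error.

The assignment is solved at the level of the four (exposure group × 30-day
death) strata. Three constraint families — both group prevalences and the
pooled crude odds ratio — leave the four stratum probabilities one degree of
freedom short, so a closure is needed: a **common within-group
stability-death odds ratio ψ** in both groups, the minimal symmetry
assumption that makes the problem well-posed and degrades gracefully at
π_de = 1 (all de-escalated stable in both outcome strata; ψ is then
determined by the continuation group alone). ψ is found by monotone 1-D
root finding (brentq on log ψ); an unattainable target reports the
attainable odds-ratio range.

Real-valued stratum probabilities become integer counts in two steps: each
group's stable total is the rounded prevalence target (so realised
prevalences are within 1/n_g of target), then the split of each total
across the death/survivor strata is chosen by an exact scan for the integer
table whose pooled odds ratio is closest to the target on the log scale,
ties broken toward the real-valued solution. On exhaustively enumerable
cohorts this provably coincides with the best feasible integer allocation,
and the realised odds ratio is always within the worst-case ±1-per-cell
rounding perturbation, which is reported numerically.

Patients are then flagged stable **in exact stratum counts**, uniformly at
random within each stratum, rather than by independent Bernoulli draws:
exact counts make the stratum totals identical across random seeds, which is
what makes the refit hazard ratios reproducible across seeds (they agree at
two-decimal reporting precision; exact identity would additionally require
the propensity score to be constant within strata). Escalated patients sit
outside the odds-ratio constraint — they are censored at escalation — but
receive a draw at the continuation-group stratum probability so their
pre-escalation person-time can carry the covariate; a flag to include them
in the constraint is not provided because the 2×2 table is defined on the
de-escalated + continuation analysis framing.

The **sweep** re-fits the propensity-adjusted Cox model with the simulated
flag as an extra baseline covariate for each π_de on a 0.01-step grid from π
to 1.00 (0.90 and 1.00 always included), repeating the random assignment
with `n_seed_repeats` seeds (default 3): the first seed's fit is reported,
the across-seed mean, SEM and spread are logged. The curve's summary is the
smallest π_de whose CI upper bound reaches 1. **Confounder strength** is the
percent change of the crude hazard ratio when one covariate is added alone,
sign preserved, computed for every baseline covariate (season as a joint
dummy block, day-1 rank as a rank-3 indicator), the propensity score, and
the simulated confounder at π_de ∈ {0.90, 1.00}.

## Synthetic cohort generator

The generator emulates a non-ICU CAP cohort of patients ≥65 y in which the
latent stability flag drives both de-escalation and death — the structure
the bias analysis assumes — with defaults set to the reference marginals:
empirical rank split 13.7/40.6/45.6%, de-escalation 16.7% of the cohort
(rank 3 ≫ rank 2), switch days on a categorical distribution over days 1–7
with median 3 and IQR 2–4, escalation ≈8%, stability prevalence 0.80
(log-odds decreasing in PSI, −0.6 per SD), and a discrete-time daily
logistic death hazard over days 1–90 with PSI and age slopes (0.30 and 0.15
per SD on the daily log-odds) and an overall 30-day mortality of 9.7% —
the weighted average of the two reference group mortalities. The true
conditional effect of de-escalation multiplies the daily death odds from
the switch day on (default hazard ratio 1: the no-causal-effect reading);
an optional second value after a cut day supports the proportional-hazards
experiments.

Four intercept-like quantities are **calibrated at generation time** by
monotone root finding against the drawn covariates: the stability intercept
(prevalence target), the de-escalation intercept (share target, weighted by
each patient's probability of surviving to the switch day, so deaths that
cancel an intended switch are already priced in), and the mortality
intercept and stability coefficient (jointly hitting the overall mortality
and the crude stability-death odds ratio). Calibration is deterministic
given the seed; infeasible targets raise an explicit error naming the
violated constraint.

One tension is inherent and worth stating: with stability as the *only*
unmeasured driver, the three stated bias parameters cap the group-mortality
contrast at roughly 5% vs 11% — the reference contrast of 3.5% vs 10.9%
cannot be reached jointly with a crude OR of 0.14 and 80% prevalence. The
generator privileges the bias parameters (they are what the simulation is
about); consequently the blinded hazard ratio on one study-sized cohort is
≈0.5 rather than ≈0.4, and single-cohort significance at ~116 events is
marginal. Tests that assert the systematic bias therefore pool replicate
cohorts by inverse variance.

What the generator does *not* emulate: inter-covariate correlation beyond
stability↔PSI (all other covariates are independent draws at their marginal
frequencies), ICU transfer, hospital-level clustering, discharge as a
competing risk, time-varying stability, or any real measurement of the
stability construct. Passing tests show that the *estimation machinery*
behaves as claimed under the assumed data-generating structure — not that
real CAP data satisfy that structure.

## The deterministic fixture

`make_fixture()` builds a 1,536-patient cohort whose classification
reproduces the reference marginals exactly: 211/624/701 rank-1/2/3 starters;
257 de-escalations (42 from rank 2, 215 from rank 3; switch-day counts
26/51/77/51/26/15/11 over days 1–7, median 3, IQR 2–4); 123 escalations (41
from rank 1, 82 from rank 2); 1,156 unchanged; 9 deaths among the
de-escalated and 107 among the 986 rank-2/3 continuation patients, spread
deterministically over days 2–29 and across both ranks; 14 later
escalations after de-escalation, disjoint from the deaths. Covariates
follow fixed modular stride patterns at the reference frequencies, so the
fixture is byte-identical across calls and model fits on it are exactly
reproducible. It carries no latent stability column: like the real data,
stability is unmeasured and only ever *injected*.

## Problem sizes and numerical choices

Analyses and tests run at the study's own scale (≈1,536 patients, ≈116
events) for model fits, 20,000 for structural checks (null recovery,
immortal time, PH diagnostics), and 100,000 for generator calibration —
sizes at which Monte-Carlo error is small relative to every asserted
margin. Root finding uses brentq with generous brackets (±30 on log scales)
and explicit infeasibility messages. The logistic fit uses L-BFGS
(Newton-Raphson is fragile when a rare comorbidity nearly separates);
coefficients above 30 in absolute value or non-convergence are treated as
separation. All randomness flows through `numpy.random.default_rng` seeds
carried in the configuration objects; the whole pipeline is a pure function
of (config, seeds), and the results JSON is byte-identical across reruns.

## Known limitations

- The closure (common within-group ψ) is an assumption; any other closure
  satisfying the three constraints would give slightly different stratum
  probabilities, though the same pooled 2×2 margins.
- Stability enters the refit as a baseline covariate despite its 72-h
  timing, and de-escalation before day 3 is allowed — both mirror the
  static-confounder simplification.
- The hazard ratio's non-collapsibility means adjusted and crude estimands
  differ even absent confounding; the strength table's percent changes mix
  confounding removal with non-collapsibility, as does any
  with-vs-without-covariate comparison.
- No competing-risk handling for discharge; censoring at day 30 treats
  post-discharge follow-up as complete, as in the source design.
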