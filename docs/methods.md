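# Methods

## The decision problem

`copdcf` evaluates whether a *systematic case-finding programme* for
undiagnosed chronic obstructive pulmonary disease (COPD) — mailing a
respiratory symptom screening questionnaire to all ever-smokers aged 50+
every three years, with confirmatory spirometry for symptomatic responders —
is good value for money compared with routine diagnosis alone in UK primary
care.  The output is a cost-utility analysis from the health-service
perspective: discounted lifetime costs (GBP) and quality-adjusted life-years
(QALYs) per cohort member under each strategy, and the incremental
cost-effectiveness ratio (ICER) between them.

## Model structure

A Markov cohort model with a 3-month cycle, a 50-year horizon (200 cycles,
maximum age 100) and 14 mutually exclusive health states:

* **disease-free**: asymptomatic; symptomatic without airflow obstruction;
* **undiagnosed COPD**: GOLD stages 1–3 (case-finding studies virtually
  never surface undiagnosed GOLD 4, so that state does not exist);
* **diagnosed, untreated COPD**: GOLD 1–4;
* **diagnosed, treated COPD**: GOLD 1–4 (on inhaled maintenance therapy);
* **dead** (absorbing).

Structural rules: disease worsens at most one GOLD stage per cycle;
diagnosis and treatment are never reversed; stage improvement is possible
only on treatment; symptomatic (but not asymptomatic) disease-free members
can develop incident COPD, entering undiagnosed GOLD 1 or 2 (72.2%/27.8%);
progression out of undiagnosed GOLD 3 presents clinically and enters
diagnosed-untreated GOLD 4, conserving mass without an undiagnosed GOLD 4
state.

The starting cohort is 52.7% male, aged 50: 43.0% asymptomatic, 48.2%
symptomatic without obstruction, and 8.8% prevalent undiagnosed COPD split
69.0/27.4/3.6 over GOLD 1–3.

## Transition construction

All disease inputs are annual probabilities (the GOLD transition matrix,
incidence, symptom onset, routine diagnosis 0.8%/yr, treatment initiation
29.3%/yr, severe-exacerbation probabilities 0.027/0.076/0.272/0.348 by
stage).  Each annual row is converted to quarterly by per-entry
competing-risks rate conversion: off-diagonal annual mass `S` yields total
quarterly exit `1 − (1 − S)^0.25`, shared among destinations in proportion
to their annual probabilities.  This keeps all entries non-negative (a
matrix fourth root need not) and recovers the annual probabilities exactly
over four independent quarters.

Treatment effects are odds ratios — mortality 0.98, severe exacerbation
0.85, progression to the next stage 0.85 — applied on the annual scale
(the scale of the source estimates) before rate conversion.  The annual
GOLD matrix's improvement entries (e.g. GOLD 2→1, 0.0510/yr) are retained
in treated states only; in undiagnosed/untreated states that mass stays
put.

Within a cycle, event ordering follows the care pathway: case-finding and
routine diagnosis first, treatment initiation next, then exacerbation with
case fatality competing against stage progression and death.  Patients
keep their start-of-cycle dynamics for the remainder of that cycle — the
newly diagnosed cannot also initiate treatment in the same three months,
and the newly treated feel treatment effects from the following cycle.
This keeps the composed one-cycle matrix free of improvement mass in every
undiagnosed/untreated row.

Severe (hospitalised) exacerbations are within-state events, not tunnel
states: each cycle a COPD-state member exacerbates with the quarterly
conversion of the annual stage probability; 7.03% of exacerbations are
fatal, entering the death entry multiplicatively alongside the clinical
death probability (survival factors multiply; total death is capped at 1
by construction).  Non-hospitalised exacerbations are out of scope.

## Mortality

Non-COPD states die at the sex-blended rate of a background life table;
COPD states instead carry the all-cause death column of the annual GOLD
matrix (0.77%–8.77%/yr by stage), so background mortality is **not** added
to them.  To avoid double counting, the COPD-attributable share is removed
from the background table before use:
`q_free = (q_all − prevalence × q_copd) / (1 − prevalence)`, with
`q_copd` the stage-mix-weighted COPD death probability and a default
background COPD prevalence of 0.09 (roughly twice a ~4.5% diagnosed
prevalence, reflecting that about half of disease is undiagnosed).  The
adjustment is floored at a small positive value where the excess
formulation would go negative (logged).

## Case-finding overlay

Every 12th cycle (3-yearly; cycle 0 included) the surviving cohort is
screened.  The cascade — questionnaire received 0.999, returned 0.355,
symptoms reported given symptomatic 1.0, spirometry attended 0.661 — is
applied per state: undiagnosed members completing it become diagnosed
(spirometry is a perfect test of true obstruction); symptomatic members
without obstruction complete spirometry and incur its cost without a
diagnosis.  Symptom reporting is conditioned on the health state rather
than re-using the trial-level aggregate reporting rate (56.4%), which
would double-count the symptom information the state already carries; the
aggregate is consistent with the ~57% symptomatic share of the cohort.
Costs per round: questionnaire £4.01 × receipt probability for every
living member (the trial mailed all flagged patients), spirometry £55.27
for the mass reaching the test.  Routine care runs the identical model
with the overlay disabled.

## Economics

Utilities: asymptomatic 0.8394, symptomatic 0.7549, GOLD 1–4
0.7197/0.7013/0.6798/0.5855 (shared by undiagnosed and diagnosed tiers),
plus 0.0367 on treatment.  A severe exacerbation costs £2,263 (inpatient
episode) and a utility decrement of 50% of the stage disutility
(−0.2398…−0.1951) for one month plus 25% for two further months — |d|/12
QALYs — charged in the event cycle (duration weighting is a configurable
multiplier).  Diagnosed states accrue annual scheduled care
(£164.56–£541.06 by stage), treated states additionally annual inhaled
medication (£485.16–£824.52), both spread evenly over the four cycles; no
cost attaches to routine care in disease-free or undiagnosed states.
Accrual uses start-of-cycle occupancy with no half-cycle correction (the
3-month cycle makes it second order; a documented limitation).  Costs and
QALYs are discounted at 3.5%/yr via `(1.035)^(−cycle/4)`.

The ICER is ΔC/ΔQ between the strategies; draws with ΔQ ≤ 0 receive
dominance labels instead of a ratio.  The probabilistic sensitivity
analysis (PSA) resamples every tabulated input from its distribution —
beta with published success/failure counts where printed; beta at a
configurable effective sample size (default 400) for probabilities and
utilities without published counts; gamma for costs, rescaled so the mean
equals the point estimate while preserving the printed shape (the printed
gamma pairs are inconsistent with the printed cost means, e.g.
questionnaire £4.01 vs 99/39 ≈ £2.54, so the point column is taken as
authoritative); lognormal for odds ratios with log-scale sigma 0.1
(their dispersion is unpublished; configurable).  Annual-matrix rows are
sampled entrywise and the stay probability recomputed as the residual;
the three starting-cohort fractions and the GOLD split are renormalised
to sum to one.  The life table is held fixed across draws.  The
cost-effectiveness acceptability curve is the fraction of draws with
nonnegative incremental net monetary benefit `λ·ΔQ − ΔC` on a £0–£50,000
grid in £500 steps (ties count as cost-effective).  Threshold analysis
bisects the parameter until the ICER is within £1 of the willingness-to-pay
value, after verifying empirical monotonicity on a 5-point scan and a sign
change at the bracket ends.

## Synthetic inputs and what they do (not) show

The published analysis drew background mortality from national life tables
and used age-specific transition matrices summarised only at age 50.
Neither source is reproduced here; instead:

* **Life table**: a deterministic Gompertz–Makeham stand-in,
  `μ(t) = a + b·c^t` with defaults `a = 2×10⁻⁴`, `b = 2.4×10⁻⁵`,
  `c = 1.10` (male annual death probability ≈ 0.003 at 50, doubling every
  7–8 years), female hazard 0.6× male, ages 40–100 with certain death at
  the terminal age.  Annual probabilities come from the exact hazard
  integral, so table survival equals `exp(−∫μ)` identically.
* **Age profiles**: log-linear multipliers `exp(slope × (age − 50))` for
  incidence, progression and COPD-state mortality, all with default slope
  0 — the age-50 point estimates apply at every age, so any age scaling is
  an explicit, visible opt-in rather than an invented default.

Consequently the packaged runs reproduce the published analysis
*structurally and directionally*, not numerically: the intervention is
costlier and more effective everywhere, the ICER falls as the screening
interval lengthens and rises as each treatment effect is switched off, and
every PSA draw lands in the north-east quadrant.  Point values differ —
the flat COPD-mortality profile in particular lets treated patients
accumulate more QALYs at older ages than an age-increasing schedule would,
producing a larger base-case QALY gain and a lower ICER than the published
point estimates.  Supplying a real life table (`LifeTable.from_csv`) and
fitted age-profile slopes moves the calibration toward the published
numbers without code changes.

## Numerical choices

* Mass conservation is asserted every cycle at 1e−9 (hard failure) and
  tested at 1e−10; matrix rows are validated to 1e−9.
* The printed annual GOLD matrix is stored verbatim; one row sums to
  1.0001 as printed, which is tolerated (5e−3) because conversions consume
  only off-diagonal entries and treat "stay" as the residual.
* Integer age indexes the life table and the age profiles, so per-strategy
  runs cache at most two matrices per year of age (screening and
  non-screening), keeping a 200-cycle run near 50 ms and the PSA tractable
  on one CPU.
* Problem sizes in the shipped analyses: 200 cycles deterministic; 2,000
  PSA draws in the acceptance script (the CLI default remains 10,000); a
  50,000-patient individual-level simulation validates the cohort engine
  in the test suite.
* Bisection tolerance £1 on the ICER; the empirical-monotonicity scan uses
  the same tolerance as slack.

## Validation

The test suite checks every structural invariant (absorbing death, no skip
deterioration, no un-diagnosis, no untreated improvement), the published
point estimates of every tabulated input, exact small-scale accrual
arithmetic, and the identities (four quarters recover an annual
probability to 1e−12; odds-ratio composition; zero-discount equivalence;
disabled case-finding equals routine care exactly).  An independent
individual-level Monte-Carlo simulator with the same event logic must
reproduce the cohort model's discounted means within 3 Monte-Carlo
standard errors at n = 50,000 for both strategies.  With every treatment
channel switched off — odds ratios 1, utility gain 0, and the
treated-only improvement entries zeroed — the strategies accrue identical
QALYs to 1e−9, confirming that diagnosis alone has no clinical effect in
the engine.

## Known limitations

* No half-cycle correction; accrual on start-of-cycle occupancy.
* Sex is a fixed blend of life-table rates, not separate cohorts.
* Default age-constant disease parameters (see above): old-age COPD
  mortality is understated relative to any real schedule.
* Exacerbation-driven hospitalisation does not itself trigger diagnosis.
* PSA draws are independent across parameters (no correlation structure),
  and the life table is not resampled.
* Treated patients never revert to untreated.
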