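# Methods

`epiflow` is a deterministic Markov cohort model of the treatment flow of
epilepsy patients in Japan, built to quantify the national budget impact
of optimizing referral from non-specialized to specialized care.  This
note documents the model, its conventions and parameters, the places
where the published description of the source analysis is ambiguous or
internally inconsistent, and what the tests do and do not establish.

## The cohort model

An incident cohort of 7117 newly diagnosed pediatric epilepsy patients
(age 5, representing onset between 0 and 10 years) enters non-specialized
monotherapy and is propagated in annual cycles as expected patient
counts over a lifetime horizon.  The state space is

* non-specialized care, 1–4 concurrent anti-seizure medications (ASMs);
* specialized care, 1–3 ASMs, plus a seizure-reduction pool and a
  difficult-to-treat (drug-resistant) pool;
* three absorbing post-surgical outcomes: long-term seizure freedom,
  significant seizure reduction, and continued difficult-to-treat.

Because an identical cohort enters every year, the annual national
cross-section equals the lifetime sum of one cohort's trace.  No death is
modelled inside the horizon; instead the horizon itself carries the
remaining-lifetime truncation.  The default horizon is **79.3982 years**,
the value implied by the published pooled population (565 077 patients /
7117 incident patients per year); the terminal fractional cycle is
weighted by its fraction (0.3982) rather than simulated sub-annually.

### Transition semantics

Two transition classes drive the model:

1. **Per-entry branches.**  Escalation to the next therapy line,
   referral to specialized care at the same line, and diversion to
   surgery are *one-time* probabilities applied at the start of the cycle
   after a patient enters a therapy state — every patient spends at least
   one full cycle per state, and branches at the same state compete on
   the same entry mass (residual mass settles permanently).  At a
   specialized line k the surgery branch ("in transition to line k+1")
   competes with escalation as a fraction of the whole entry mass; the
   third specialized escalation terminates in the difficult-to-treat
   pool.  These conventions were fixed by requiring the engine to
   reproduce the published patient-distribution table: with them, the
   published early-phase surgery counts (14/27/25 current, 142/164/267
   optimized) and the non-specialized four-drug population (8766) are
   reproduced to ~1% or better; plausible alternatives (branches firing
   in the entry cycle, surgery as a sub-fraction of escalators) miss by
   2× on surgery counts or several percent on occupancy.

2. **Windowed annual transitions.**  Late referral (non-specialized
   four-drug → difficult-to-treat) and late surgery (difficult-to-treat →
   operation) apply each year at 1.5%/year within a 40-year window
   clocked from *entry into the state* (following the parameter table's
   heading; the methods prose says "from onset", and the engine exposes
   `late_window_clock="onset"` as an option — the entry clock fits the
   published four-drug population to +0.05%, the onset clock to +2%).
   Counter-referral of settled specialized-care patients back to primary
   care at the same line applies for the first 5 years after settling
   (implemented as tunnel ages, i.e. time-in-state bookkeeping);
   counter-referred patients arrive stable and are not re-exposed to the
   non-specialized entry branches.

Surgery is a one-cycle event: the operation year occupies a separate
ledger row (by therapy line at surgery: mono, two, three-immediate, or
"successive" from the difficult-to-treat pool), and survivors are
deposited into the post-surgical outcomes at the start of the next cycle.
The curative/palliative mix uses the line-specific surgery-type split
(late operations use the three-drug split, the only one published for
that pathway).  Post-surgical outcome probabilities are combined as
conditional layers — freedom `f`, reduction `(1-f)·r`, difficult
`(1-f)(1-r)` — which matches the outcome mix implied by the published
after-surgery cost rows (~0.30/0.25/0.45), where a subtractive reading
(`r - f` for reduction) does not (~0.30/0.16/0.54).

### Parameter conventions worth knowing

* **Counter-referral rates.**  The published "annual transition
  probability in 5 years" column is internally inconsistent: the current
  flow's 1.0% values reproduce the published specialized-care pools only
  when read as *annual* probabilities, while the optimized flow's
  80/50/20% reproduce them only as *5-year cumulative* probabilities
  (annual = total/5).  The bundled files therefore carry the current flow
  as annual rates and the optimized flow as window totals; the loader
  accepts either key (`counter_referral_annual`,
  `counter_referral_window_total`).

* **Seizure-reduction inflow** (`reduction_inflow_annual`).  The
  published optimized flow contains ~22 000 seizure-reduction patients of
  whom only ~11 000 are attributable to surgery, so the source model has
  a non-surgical route into seizure reduction that its main text never
  parameterizes.  It is implemented as an annual difficult-to-treat →
  seizure-reduction probability on the same 40-year window, competing
  with late surgery.  The bundled values (current 0.002479, optimized
  0.021563) were obtained with the package's own calibration utility so
  that each flow reproduces its published annual surgery count (372 and
  701) — the same procedure the source analysis states for its own
  calibrated probabilities.  With the inflow at zero the engine yields
  386 and 755 surgeries/year instead.

* **Ages and cost bands.**  Cycle t corresponds to age 4 + t.  Annual
  pharmacotherapy cost is 4× the 3-month cost at the cycle's age band
  (pediatric ≤ 6, pediatric > 6, adult).  The published cost table never
  says where "adult" begins; `adult_age_threshold` defaults to 15
  (aligned with the surgery table's 15–19 band), which gives the best
  row-level agreement in a scan over 13–20, and the headline is nearly
  insensitive to it.  Surgery cost uses the four published operation
  bands, and each operation is additionally costed with one year of
  pharmacotherapy at the origin state's rate (this reproduces the
  published surgery cost block to ~1%; the operation fee alone
  under-counts it by ~20%).

* **Published table layout.**  In the patient-distribution table the
  post-surgical patients are carried inside the printed rows (seizure
  free within non-specialized monotherapy — primary-care maintenance —
  reduction and difficult within the corresponding specialized rows, and
  the surgery row as one patient-year per operation); this is the only
  mapping consistent with both scenarios' printed row totals, which equal
  cohort × horizon exactly.  In the cost table the post-surgical pools
  are costed in a separate after-surgery block, seizure-free patients at
  the specialized monotherapy rate.

## Reproduction quality and a documented residual

With the shipped scenario files the engine reproduces the published
base-case tables to ~0.1–2% on nearly every row (four-drug population
8770 vs 8766; surgery counts exact by calibration; current-flow total
cost +0.01%).  The one headline residual: the model's total annual cost
difference is **−9 946 million JPY vs the printed −9 548** (−4.2%).  This
cannot be closed consistently, because the published cost table is
internally inconsistent — its printed grand totals exceed the sums of
its own printed rows by 391 (current) and 1 911 million JPY (optimized),
and the difference of its printed block subtotals is −11 068.  A model
whose rows sum to its totals necessarily lands between the two published
figures.  No parameter is tuned against the printed headline.

The one-way sensitivity analysis reproduces the published qualitative
findings: the current-flow mono→two-drug escalation probability is the
most influential parameter, and no parameter's worst bound turns the
saving into a cost.  The published single worst-case figure (−470
million JPY) is of the same order as, but not equal to, the model's
(−1 315 million JPY at the ±20% bound); the published bound construction
for that figure is not stated precisely enough to match.

## Claims-based estimation

The prescription-database stage estimates the non-specialized escalation
probabilities from dispensing records: episodes start at a prescription
preceded by ≥6 months without ASM supply (the treatment-free gap is
measured from the end of the last dispensed supply, so quarterly refills
do not fragment episodes), run for 36 months, and the therapy line is
the running maximum of the same-date distinct-ASM count (an add-on in a
same-date prescription escalates; dropping a drug never de-escalates).
Fixed-length months are used (6 months = 183 days, 36 months = 1096
days).  Escalation probability k is the fraction of episodes reaching
line k that reach line k+1 within follow-up, reported with
numerators/denominators; zero denominators report as missing, never as
zero.  Combination costs are frequency-weighted means over same-date
combinations of exactly n whitelist drugs (n = 2, 3, 4), excluding any
combination containing a non-whitelist drug and any set of ≥5 drugs,
with prices normalized to 90 days of supply.

## What the synthetic data do and do not show

The synthetic claims generator emulates the structure the estimators
rely on — washout-clean index dates, 90-day same-date combination
refills, uniformly timed escalations with known per-line probabilities,
and a configurable noise fraction (5% default) of non-whitelist
co-medication and post-window dispensings.  It does **not** emulate real
prescribing: irregular visit cadence, partial adherence, drug switches
at constant line, regional pricing, or informative censoring.  Passing
the recovery tests (estimates within 3 Monte-Carlo standard errors of
truth at n = 20 000, and at smaller n) therefore establishes the
correctness of the episode logic and estimator arithmetic, not the
validity of the published point estimates on the real extract, which is
not redistributable.  The actual ASM whitelist ("top eight frequently
prescribed plus three recently approved") is likewise not published, so
the default whitelist is a labelled synthetic stand-in.

## Numerical and design choices

* Expected-value propagation with float64; occupancy conservation per
  cycle is exact to ~1e-8 of the cohort and asserted in tests; the
  engine agrees with explicit matrix powers to 1e-10 per cell on
  time-homogeneous plans.
* Calibration is a one-dimensional common-multiplier bisection (monotone
  response verified at three bracket points, either direction accepted;
  multipliers that clip probabilities past their joint branch bounds are
  treated as infeasible and shrink the bracket).  Multi-parameter
  fitting is deliberately out of scope.
* Sensitivity bounds: ±20% (default) or ±1.96 × 0.1 × point estimate
  ("ci95") — the source states both without reconciling them.  Clinical
  parameters are perturbed per flow; cost entries and the incident
  cohort size are shared national quantities and are perturbed jointly.
  Probabilities pushed past 1 are clipped with a logged warning.
  The comparison horizon is not perturbed (a comparison across unequal
  horizons is undefined).
* Degenerate inputs: an all-zero scenario freezes the cohort in entry
  monotherapy; a zero surgery count reports the early-phase share as
  undefined rather than 0.

## Known limitations

Adverse-event costs, quality-of-life weighting, indirect costs,
discounting (the source applies none), pediatric self-limited epilepsy,
seizure recurrence and re-operation are all outside the model, as in the
source analysis.  The exact supplementary state topology of the source
model is unpublished; the conventions above reproduce its printed tables
closely but are reverse-engineered, and rows that depend on the
unpublished seizure-reduction pathway (the specialized "seizure
reduction" and "difficult-to-treat" splits) carry the largest residuals
(~6–10%).
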