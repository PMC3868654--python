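# Methods

## Model structure and assumptions

The package implements a deterministic, expectation-based cohort model of a
prescription-to-OTC switch for one triptan, evaluated over a one-year
horizon at forecast peak OTC uptake. There is no patient-level simulation
and no discounting; every quantity is a product of segment sizes, annual
event rates and unit costs, so all results are exactly reproducible and
linear in the population. Health outcomes (QALYs, clinical endpoints) are
deliberately out of scope: only the economic consequences of serious
adverse events and medication-overuse headache (MOH) are priced.
Patients on non-triptan Rx drugs are excluded from all cost flows.

The population cascade multiplies the national population by the adult
fraction and migraine prevalence, then splits by diagnosis rate, treatment
rate and prescription status into six segments (Pop 1–6, see README).
Segment sizes are kept fractional internally; rounding to whole persons or
currency units is purely a display operation (half-up). Country fixtures
carry explicit `segment_overrides` for Pop 1/Pop 2 because the published
counts were calibrated against sales data and are not recoverable from the
rounded cascade percentages (France: cascade gives 307,217 vs the published
309,354).

## Accrual rules

Rules the published tables imply but do not state explicitly; each was
validated cell-by-cell against the published six-country results:

* **Drug acquisition** is payer-borne spend only: segment size × 24
  attacks × unit cost per attack × reimbursement rate. Switchers' OTC
  purchases leave the payer budget and are *not* added back to societal
  costs (the published societal totals equal TPP + the four indirect
  components exactly). Under disreimbursement (scenario D) Pop 1
  non-switchers are re-prescribed other, still-reimbursed triptans.
* **ER visits** are priced at the raw 0.4%/attack probability for all six
  segments at baseline — applying the 65% triptan reduction to Pop 1/2 at
  baseline does not reproduce the published UK/Poland cells; the
  no-reduction baseline does, to <0.01%. Savings accrue the 65% reduction
  to OTC-side switchers (Pop 3–6) for all their attacks and to Pop 1/2
  switchers for the 25% of attacks when the Rx product was not at hand.
* **Cardiovascular events** accrue to newly OTC-exposed switchers
  (Pop 3–6) only; Pop 1/2 switchers are already screened. Reproduces the
  published France (872) and Italy (654) cells exactly.
* **MOH** (extra GP visits and extra attack days) accrues to Pop 4
  switchers only — newly medicated patients. The published input table
  names Pop 3/5/6 for the mitigation row, but the published cost cells are
  arithmetic on Pop 4 (verified for France, UK and Poland to the unit);
  the cost arithmetic wins.
* **Productivity** uses human-capital weights per work-hour attack day:
  baseline loss weight `α + π(1−λ)` (absenteeism days plus presenteeism
  productivity shortfall at productivity level λ = 0.56), savings weight
  `g·[αλ + π(1−λ)]` with the 13% triptan effectiveness gain `g`, scaled by
  the 35% work-hour attack share and 70% employment. The savings weight is
  a reconstruction chosen because it reproduces the published Pop 3&4
  savings cell for France exactly (939,832) and the UK cell to 0.3%.
* Scenario switch-rate generalisation: ER and productivity savings formulas
  treat Pop 5/6 switchers like Pop 3/4 switchers. This is invisible in the
  base case (s₅=s₆=0) but is required to reproduce the published
  sensitivity result that undiagnosed-switcher scenarios are favourable in
  every country (UK payer savings share 12.34% → 12.43%; this model gives
  12.44%).

## Known residuals vs the published tables

Three components cannot be reconstructed exactly from the printed inputs;
they are documented rather than fudged, and the test suite holds them to
tolerance bands instead of strict equality:

| quantity | published | this model | residual |
|---|---|---|---|
| France ER baseline | 10,426,799 | 10,364,611 | 0.6% |
| France Pop 1&2 productivity baseline | 361,321,298 | 365,673,939 | 1.2% |
| France Pop 1&2 productivity savings | 1,811,037 | 1,929,627 | 6.5% |
| France MOH productivity after | 233,411 | 265,390 | 14% |

The exactly-reproducible cells (GP, time off work, CV, MOH-GP, Pop 3&4
productivity savings; drug and ER to <0.01%) are asserted strictly. The
six-country payer savings aggregate lands at €75.33M vs the published
€75.30M. A handful of published cascade cells ("Treated patients" for
France/UK) are floor- rather than half-up-rounded; cascade tests allow ±1
person on those rows.

## Parameters

All rates are stored as proportions in [0,1]; files may use percent strings
("21.3%"), converted at parse time. Behavioural constants shared across
countries (attack frequencies 24/12 per year, GP visit rate 2.8/year, 30%
unscheduled-visit share, ER 0.4%/attack and 65% reduction, 8%
contraindicated × 0.1% serious-AE incidence × 95% mitigation, productivity
weights, MOH risk 14% × 95% mitigation × 8.4 visits × 108 attack days) live
in `data/shared.yaml`; country files carry only the country-specific unit
costs, reimbursement rates and cascade rates, and override shared keys if
present. Currency is tracked per country (EUR, GBP, PLN) and converted only
at aggregation/reporting, at the fixed 2010 rates €1 = £0.83 = PLN 4.07.
Scenario C's weaker mitigation (90%) applies to the cardiovascular risk
only, not to MOH mitigation.

## Synthetic parameters and the oracle

`synthetic.generate_country(seed, scale)` draws a valid parameter set with
every rate inside the range spanned by the six study countries (prevalence
0.10–0.213, diagnosis 0.50–0.75, reimbursement ∈ {0, 65%, 100%}, unit costs
inside the observed cost spans) — realistic for Western/Central European
settings, deterministic per seed. It emulates the schema and plausibility
of real country files, not real-world correlation between rates (e.g. price
levels and wage levels are drawn independently), so passing tests show
formula correctness across the parameter space, not calibration to any new
country.

`synthetic.brute_force_costs` is an independent per-patient enumeration of
every accrual rule; because the engine is linear in segment sizes the two
routes must agree on integer cohorts, and the suite (and the acceptance
script's self-check) asserts agreement at 1e-12 relative tolerance —
repeated addition versus `n × x` multiplication differ in the last ulp, so
"exact" means machine precision.

## Numerical choices

* Full floating-point precision end to end; half-up rounding (Decimal,
  ties away from zero) only at display.
* "After" GP and time-off costs are computed as `before − avoided` so that
  zero switch rates give exactly zero savings (no catastrophic-cancellation
  artefacts in the zero-scenario invariants).
* Degenerate inputs: zero prevalence (or any zero cascade rate) yields an
  empty cohort and zero costs; zero reimbursement (Poland) yields zero
  payer drug spend in every scenario, rendered as blank table cells;
  mitigation = 1 removes the corresponding risk cost entirely.
* Problem sizes: the model is nine products per component per country —
  a full six-country, five-scenario sweep runs in well under a second, and
  the test suite's 100-cohort oracle sweep uses cohorts of ≤60 patients.

## Limitations

One-year static horizon (no uptake dynamics, no multi-year cohort), no
probabilistic sensitivity analysis (the scenario engine is the deliberate
extension point), identical switch rates across countries, and no modelling
of misdiagnosis, substitution toward other Rx drugs, or disease-awareness
effects. The four residual cells above mean aggregate societal savings
carry a ~1% reconstruction uncertainty even with the published inputs.
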