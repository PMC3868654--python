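# otcswitch

A deterministic budget-impact model of a migraine triptan Rx-to-OTC switch
in six EU countries (France, UK, Italy, Germany, Poland, Spain), for health
economists and payers who want the published desk model as tested, reusable,
parameter-driven code rather than a spreadsheet.

## The model

Migraine sufferers in each country are split by an epidemiological cascade
into six treatment-status segments:

| segment | status |
|---|---|
| Pop 1 | diagnosed, on the Rx triptan to be switched |
| Pop 2 | diagnosed, on other Rx triptans |
| Pop 3 | diagnosed, self-treating with OTC products |
| Pop 4 | diagnosed, untreated |
| Pop 5 | undiagnosed, self-treating with OTC |
| Pop 6 | undiagnosed, untreated |

with, e.g., adults with migraine `N = population × f₁₈ × prevalence`,
`diagnosed = N × d`, `treated = diagnosed × t`, and so on. At forecast peak
OTC uptake a fraction *sᵢ* of each segment switches to the OTC triptan
(base case: 20/20/3/3/0/0 %). Nine annual cost components are priced before
and after the switch over a one-year horizon, in local currency:

* **payer (TPP) perspective** — reimbursed drug acquisition
  (`Popᵢ × 24 attacks × unit cost × reimbursement rate`), GP visits
  (2.8/patient/year, of which 30% are prescription-only and avoided by
  switchers), ER visits (0.4% per attack, −65% with triptan access),
  serious cardiovascular events among newly OTC-exposed switchers
  (8% contraindicated × 0.1% incidence × (1−95% mitigation)), and extra GP
  visits from medication-overuse headache (MOH) in newly treated switchers;
* **societal perspective** — TPP plus work time lost to GP visits, and
  absenteeism/presenteeism productivity losses on attack days
  (human-capital weights `α + π(1−λ)` per work-hour attack day), including
  extra MOH attack days.

Savings are `before − after` per component; the adverse-event and MOH
components only exist after the switch, so their "savings" are negative.
Scenarios A–D vary the switch rates, the risk-mitigation rate and the
reimbursement policy (disreimbursement). Country totals are aggregated in
€2010 (£0.83/€, PLN 4.07/€).

All model inputs ship as YAML fixtures transcribing the published tables;
user files with the same schema can replace any country.

## Worked example

```sh
$ otcswitch cascade FR
                                                      row    persons
                          Adults with migraine population 10,403,103
                                       Diagnosed patients  7,802,327
                                         Treated patients  7,022,095
              Adults treated with Rx (w or w/o OTC drugs)  3,511,047
Pop 1 (diagnosed, treated with Rx triptan to be switched)    309,354
...
```

```sh
$ otcswitch run --scenario base --countries FR --format csv
country,row,Drug acquisition,GP visits,ER visits,...
FR (EUR 2010),Costs before the switch,89289192,53749696,10364611,0,0,...
FR (EUR 2010),Costs after the switch,71431354,50524714,10196136,872,30279,...
FR (EUR 2010),Total savings,17857838,3224982,168476,-872,-30279,...
```

Reading the savings row: shifting 20% of Rx-triptan patients to OTC takes
€17.9M of drug spend off the French payer budget and avoids €3.2M of GP
visits and €0.17M of ER visits, at the price of €872 of additional
cardiovascular-event costs and €30k of MOH-related GP visits — €21.2M of
annual payer savings. Across all six countries the base case yields about
€75M of payer savings (`otcswitch run` with the default country list), about
13% of the €582M pre-switch direct spend.

The library API mirrors the CLI:

```python
from otcswitch import builtin_parameters, builtin_scenarios, run_scenario

p = builtin_parameters()
run = run_scenario(builtin_scenarios()["base"], p.epidemiology, p.resources)
run.totals_eur2010["tpp"]["savings"]   # 75329922.2...
```

`otcswitch synth --seed 1 --scale 1000000` emits a random but valid synthetic
country file for pipeline testing.

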