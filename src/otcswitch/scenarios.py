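"""Run the model across countries and scenarios; aggregate in 2010 euros."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .costs import BudgetImpactResult, evaluate_country
from .parameters import (
    CountryEpidemiology,
    CurrencyTable,
    ResourceParams,
    SwitchScenario,
)

__all__ = ["ScenarioRun", "run_scenario", "compare_scenarios"]

_PERSPECTIVES = ("tpp", "societal")
_STATES = ("before", "after", "savings")


@dataclass
class ScenarioRun:
    """Per-country results plus euro-converted aggregates for one scenario."""

    scenario: SwitchScenario
    results: dict[str, BudgetImpactResult]
    currency_table: CurrencyTable = field(default_factory=CurrencyTable)

    @property
    def totals_eur2010(self) -> dict[str, dict[str, float]]:
        """``{perspective: {before/after/savings: EUR amount}}`` over all countries."""
        totals = {p: dict.fromkeys(_STATES, 0.0) for p in _PERSPECTIVES}
        for res in self.results.values():
            for p in _PERSPECTIVES:
                for st in _STATES:
                    local = getattr(res, f"{p}_{st}")
                    totals[p][st] += self.currency_table.to_eur(local, res.currency)
        return totals


def run_scenario(
    sc: SwitchScenario,
    epi_by_country: Mapping[str, CountryEpidemiology],
    rp_by_country: Mapping[str, ResourceParams],
    currency_table: CurrencyTable | None = None,
) -> ScenarioRun:
    """Evaluate one scenario for every country in ``epi_by_country``."""
    if not epi_by_country:
        raise ValueError("at least one country is required")
    missing = sorted(set(epi_by_country) - set(rp_by_country))
    if missing:
        raise ValueError(f"missing resource parameters for countries: {missing}")
    results = {
        code: evaluate_country(epi, rp_by_country[code], sc)
        for code, epi in epi_by_country.items()
    }
    return ScenarioRun(sc, results, currency_table or CurrencyTable())


def compare_scenarios(runs: Iterable[ScenarioRun]) -> pd.DataFrame:
    """Tabulate euro savings and percent-of-baseline-spend across scenarios.

    All runs must cover the same country set.  Returns one row per scenario
    with absolute EUR-2010 savings and savings as a percentage of pre-switch
    spend, for both perspectives.
    """
    runs = list(runs)
    if len(runs) < 2:
        raise ValueError("need at least two scenario runs to compare")
    country_sets = [frozenset(r.results) for r in runs]
    if len(set(country_sets)) != 1:
        raise ValueError(
            "scenario runs cover different country sets: "
            + ", ".join(sorted(map(str, {tuple(sorted(s)) for s in country_sets})))
        )
    rows = []
    for run in runs:
        totals = run.totals_eur2010
        row: dict[str, object] = {"scenario": run.scenario.name}
        for p in _PERSPECTIVES:
            before, savings = totals[p]["before"], totals[p]["savings"]
            row[f"{p}_savings_eur"] = savings
            row[f"{p}_savings_pct"] = 100.0 * savings / before if before else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")
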