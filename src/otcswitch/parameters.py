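"""Parameter models, validation and YAML I/O for the switch model.

The model is entirely parameter-driven: one YAML file per country carries the
epidemiological cascade rates and the country-specific unit costs, a shared
file carries the behavioural constants that are common to all countries
(attack frequencies, visit probabilities, productivity weights), and a
scenarios file carries the switch-rate scenarios.  Rates may be written either
as proportions (``0.213``) or percent strings (``"21.3%"``); they are
normalised to proportions at parse time.

Packaged fixtures for France, the UK, Italy, Germany, Poland and Spain
transcribe the published model inputs verbatim.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Annotated, Any, Optional

import yaml
from pydantic import (
    BaseModel,
    BeforeValidator,
    ConfigDict,
    Field,
    model_validator,
)

__all__ = [
    "CountryEpidemiology",
    "ResourceParams",
    "SwitchScenario",
    "SegmentOverrides",
    "CurrencyTable",
    "ParameterSet",
    "load_country",
    "save_country",
    "load_parameters",
    "load_scenarios",
    "builtin_parameters",
    "builtin_scenarios",
    "BUILTIN_COUNTRY_FILES",
]

#: country code -> packaged fixture file name
BUILTIN_COUNTRY_FILES = {
    "FR": "france.yaml",
    "UK": "uk.yaml",
    "IT": "italy.yaml",
    "DE": "germany.yaml",
    "PL": "poland.yaml",
    "ES": "spain.yaml",
}


def _parse_rate(value: Any) -> Any:
    """Accept ``0.213``, ``"0.213"`` or ``"21.3%"``; return a proportion."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            return float(text[:-1].replace(",", "")) / 100.0
        return float(text)
    return value


# a rate constrained to [0, 1], percent notation allowed in files
Proportion = Annotated[float, BeforeValidator(_parse_rate), Field(ge=0.0, le=1.0)]
NonNegative = Annotated[float, Field(ge=0.0)]


class _StrictModel(BaseModel):
    """Base with unknown-key rejection; all parameter models inherit it."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SegmentOverrides(_StrictModel):
    """Explicit segment sizes replacing cascade-derived values.

    The published Pop 1/Pop 2 counts were calibrated against sales data and do
    not reproduce exactly from the rounded cascade percentages, so fixtures
    carry them as overrides.  Any subset of the six segments may be given.
    """

    pop1: Optional[NonNegative] = None
    pop2: Optional[NonNegative] = None
    pop3: Optional[NonNegative] = None
    pop4: Optional[NonNegative] = None
    pop5: Optional[NonNegative] = None
    pop6: Optional[NonNegative] = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.model_dump().items() if v is not None}


class CountryEpidemiology(_StrictModel):
    """Population cascade rates for one country.

    The cascade runs: total population -> adults -> adults with migraine ->
    diagnosed -> treated -> Rx-treated -> triptan users -> users of the
    to-be-switched triptan.  Undiagnosed patients split into OTC-self-treated
    and untreated using ``undiagnosed_treated_fraction``.
    """

    country_code: str
    population_size: float = Field(gt=0.0)
    fraction_over_18: Proportion
    migraine_prevalence: Proportion
    diagnosis_rate: Proportion
    treated_fraction: Proportion
    rx_treated_fraction: Proportion
    triptan_fraction: Proportion
    switched_triptan_fraction: Proportion
    undiagnosed_treated_fraction: Proportion
    segment_overrides: Optional[SegmentOverrides] = None

    @property
    def rx_treated_adults(self) -> float:
        """Adults on Rx treatment derived from the cascade (no overrides)."""
        return (
            self.population_size
            * self.fraction_over_18
            * self.migraine_prevalence
            * self.diagnosis_rate
            * self.treated_fraction
            * self.rx_treated_fraction
        )

    @model_validator(mode="after")
    def _check_overrides(self) -> "CountryEpidemiology":
        if self.segment_overrides is not None:
            ov = self.segment_overrides.as_dict()
            pop1 = ov.get("pop1")
            pop2 = ov.get("pop2")
            if pop1 is not None and pop2 is not None:
                # 5% tolerance: printed segment counts are rounded/calibrated
                if pop1 + pop2 > 1.05 * self.rx_treated_adults:
                    raise ValueError(
                        "segment_overrides: pop1 + pop2 exceeds the Rx-treated "
                        "adults implied by the cascade by more than 5% "
                        f"({pop1 + pop2:.0f} > 1.05 * {self.rx_treated_adults:.0f})"
                    )
        return self


class ResourceParams(_StrictModel):
    """Unit costs, event probabilities and productivity weights.

    Country-specific rows (unit costs, reimbursement rates, currency) have no
    defaults and must come from the country file; behavioural constants shared
    across all six countries default to the published base-case values and
    live in the shared parameter block.
    """

    country_code: str
    currency: str = "EUR"

    # drug acquisition
    unit_cost_switched_triptan: NonNegative
    unit_cost_other_triptan: NonNegative
    reimb_rate_switched: Proportion
    reimb_rate_other: Proportion

    # visit / event unit costs
    gp_visit_cost: NonNegative
    er_visit_cost: NonNegative
    ae_event_cost: NonNegative
    workday_cost: NonNegative

    # attack frequency
    attacks_per_year_rx: NonNegative = 24.0
    attacks_per_year_otc: NonNegative = 12.0

    # GP visits
    gp_visits_per_year: NonNegative = 2.8
    unscheduled_visit_fraction: Proportion = 0.30

    # emergency room
    er_prob_per_attack: Proportion = 0.004
    er_reduction_triptan: Proportion = 0.65

    # serious cardiovascular adverse events
    contraindicated_fraction: Proportion = 0.08
    serious_ae_incidence: Proportion = 0.001
    ae_mitigation: Proportion = 0.95

    # productivity
    work_hour_attack_fraction: Proportion = 0.35
    prob_no_triptan_at_attack: Proportion = 0.25
    absenteeism_rx: Proportion = 0.24
    absenteeism_otc: Proportion = 0.08
    presenteeism_rx: Proportion = 0.73
    presenteeism_otc: Proportion = 0.24
    productivity_level: Proportion = 0.56
    triptan_productivity_gain: Proportion = 0.13
    employed_fraction: Proportion = 0.70

    # time off work for GP visits
    gp_visit_workdays_lost: NonNegative = 0.5
    gp_visit_during_work_fraction: Proportion = 0.25

    # medication-overuse headache
    moh_risk: Proportion = 0.14
    moh_mitigation: Proportion = 0.95
    moh_extra_gp_visits: NonNegative = 8.4
    moh_extra_attack_days: NonNegative = 108.0
    moh_absenteeism: Proportion = 0.24
    moh_presenteeism: Proportion = 0.55

    @model_validator(mode="after")
    def _check_attack_rates(self) -> "ResourceParams":
        if self.attacks_per_year_rx < self.attacks_per_year_otc:
            raise ValueError(
                "attacks_per_year_rx must be >= attacks_per_year_otc "
                f"({self.attacks_per_year_rx} < {self.attacks_per_year_otc})"
            )
        return self


class SwitchScenario(_StrictModel):
    """Switch rates for the six segments plus policy flags.

    ``switch_rates`` holds s1..s6, the fraction of each segment adopting the
    OTC product at forecast peak uptake.  ``disreimbursement`` models removal
    of the Rx (reimbursed) status: Pop 1 non-switchers are re-prescribed other
    Rx triptans.  ``ae_mitigation_override`` replaces the adverse-event risk
    mitigation rate (labelling / pharmacist training effectiveness).
    """

    name: str
    switch_rates: tuple[
        Proportion, Proportion, Proportion, Proportion, Proportion, Proportion
    ]
    disreimbursement: bool = False
    ae_mitigation_override: Optional[Proportion] = None

    def rate(self, segment: int) -> float:
        """Switch rate for segment 1..6."""
        if not 1 <= segment <= 6:
            raise ValueError(f"segment must be 1..6, got {segment}")
        return self.switch_rates[segment - 1]


class CurrencyTable(_StrictModel):
    """Local-currency units per euro (2010 exchange rates)."""

    rates: dict[str, float] = {"EUR": 1.0, "GBP": 0.83, "PLN": 4.07}

    @model_validator(mode="after")
    def _check_eur(self) -> "CurrencyTable":
        if self.rates.get("EUR") != 1.0:
            raise ValueError("rate for EUR must be exactly 1")
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("exchange rates must be positive")
        return self

    def to_eur(self, amount: float, currency: str) -> float:
        try:
            return amount / self.rates[currency]
        except KeyError:
            raise ValueError(f"no exchange rate for currency {currency!r}") from None


@dataclasses.dataclass
class ParameterSet:
    """A loaded set of country parameters plus scenarios, keyed by code/name."""

    epidemiology: dict[str, CountryEpidemiology]
    resources: dict[str, ResourceParams]
    scenarios: dict[str, SwitchScenario]

    @property
    def country_codes(self) -> list[str]:
        return list(self.epidemiology)


# ---------------------------------------------------------------------------
# YAML I/O


def _load_yaml(path: Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return doc


def _shared_resources(doc: dict, path: Path) -> dict:
    unknown = set(doc) - {"resources"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    block = doc.get("resources", {})
    if not isinstance(block, dict):
        raise ValueError(f"{path}: 'resources' must be a mapping")
    return block


def load_country(
    path: str | Path, shared: dict | None = None
) -> tuple[CountryEpidemiology, ResourceParams]:
    """Load one country parameter file, merging in shared behavioural values.

    The country file's ``resources`` block overrides any key from ``shared``.
    Raises ``ValueError``/``pydantic.ValidationError`` naming the offending
    key on schema violations.
    """
    path = Path(path)
    doc = _load_yaml(path)
    allowed = {"country_code", "country_name", "currency", "epidemiology", "resources"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    for key in ("country_code", "epidemiology", "resources"):
        if key not in doc:
            raise ValueError(f"{path}: missing required key {key!r}")

    code = doc["country_code"]
    epi = CountryEpidemiology(country_code=code, **doc["epidemiology"])
    merged = dict(shared or {})
    merged.update(doc["resources"])
    rp = ResourceParams(
        country_code=code, currency=doc.get("currency", "EUR"), **merged
    )
    return epi, rp


def save_country(
    path: str | Path, epi: CountryEpidemiology, rp: ResourceParams
) -> None:
    """Write a self-contained country file (shared values inlined).

    ``load_country`` on the result returns parameters equal to the inputs.
    """
    epi_doc = epi.model_dump(exclude_none=True)
    epi_doc.pop("country_code")
    if epi.segment_overrides is not None:
        epi_doc["segment_overrides"] = epi.segment_overrides.as_dict()
    rp_doc = rp.model_dump()
    rp_doc.pop("country_code")
    currency = rp_doc.pop("currency")
    doc = {
        "country_code": epi.country_code,
        "currency": currency,
        "epidemiology": epi_doc,
        "resources": rp_doc,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenarios(path: str | Path) -> dict[str, SwitchScenario]:
    """Load a scenarios file: ``scenarios: [{name, switch_rates, ...}, ...]``."""
    path = Path(path)
    doc = _load_yaml(path)
    unknown = set(doc) - {"scenarios"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    out: dict[str, SwitchScenario] = {}
    for entry in doc.get("scenarios", []):
        sc = SwitchScenario(**entry)
        if sc.name in out:
            raise ValueError(f"{path}: duplicate scenario name {sc.name!r}")
        out[sc.name] = sc
    return out


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter directory: shared.yaml, scenarios.yaml, country files.

    ``shared.yaml`` and ``scenarios.yaml`` are optional; every other ``*.yaml``
    file is treated as a country file.
    """
    path = Path(path)
    if not path.is_dir():
        raise ValueError(f"{path}: expected a parameter directory")
    shared_path = path / "shared.yaml"
    shared = _shared_resources(_load_yaml(shared_path), shared_path) if shared_path.exists() else {}
    scenarios_path = path / "scenarios.yaml"
    scenarios = load_scenarios(scenarios_path) if scenarios_path.exists() else {}

    epi_by_country: dict[str, CountryEpidemiology] = {}
    rp_by_country: dict[str, ResourceParams] = {}
    for f in sorted(path.glob("*.yaml")):
        if f.name in ("shared.yaml", "scenarios.yaml"):
            continue
        epi, rp = load_country(f, shared=shared)
        if epi.country_code in epi_by_country:
            raise ValueError(f"duplicate country code {epi.country_code!r} in {f}")
        epi_by_country[epi.country_code] = epi
        rp_by_country[epi.country_code] = rp
    return ParameterSet(epi_by_country, rp_by_country, scenarios)


def _data_dir() -> Path:
    return Path(str(resources.files("otcswitch").joinpath("data")))


def builtin_parameters() -> ParameterSet:
    """The packaged six-country base-case parameter set."""
    return load_parameters(_data_dir())


def builtin_scenarios() -> dict[str, SwitchScenario]:
    """The packaged scenarios: base case plus sensitivity scenarios A-D."""
    return load_scenarios(_data_dir() / "scenarios.yaml")
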