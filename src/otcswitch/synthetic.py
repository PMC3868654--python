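"""Synthetic parameter sets and a per-patient brute-force cost oracle.

``generate_country`` draws a random but valid country parameter set whose
rates stay inside the ranges spanned by the six study countries, so every
pipeline stage can be exercised without the packaged fixtures.

``brute_force_costs`` recomputes every cost component by summing expected
per-patient annual costs over an explicit patient list.  The cost engine is
linear in the segment sizes, so on a cohort built from integer segment counts
the two routes must agree to machine precision; the oracle is written as
per-patient accrual rules, independently of the engine's vectorised algebra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .costs import ComponentCosts
from .parameters import CountryEpidemiology, ResourceParams, SwitchScenario

__all__ = ["generate_country", "brute_force_costs", "BruteForceResult"]

# rate ranges spanned by the six study countries
_EPI_RANGES = {
    "fraction_over_18": (0.77, 0.84),
    "migraine_prevalence": (0.10, 0.213),
    "diagnosis_rate": (0.50, 0.75),
    "treated_fraction": (0.89, 0.90),
    "rx_treated_fraction": (0.41, 0.50),
    "triptan_fraction": (0.05, 0.31),
    "switched_triptan_fraction": (0.03, 0.35),
    "undiagnosed_treated_fraction": (0.89, 0.90),
}
_COST_RANGES = {
    "unit_cost_switched_triptan": (6.46, 16.6),
    "unit_cost_other_triptan": (5.59, 19.87),
    "gp_visit_cost": (21.0, 39.0),
    "er_visit_cost": (25.0, 147.0),
    "ae_event_cost": (1694.0, 4320.0),
    "workday_cost": (94.0, 180.0),
}
_REIMB_LEVELS = (0.0, 0.65, 1.0)


def generate_country(
    seed: int, scale: float = 1e6
) -> tuple[CountryEpidemiology, ResourceParams]:
    """Draw a valid synthetic country (deterministic for a fixed seed).

    ``scale`` is the total national population; at least 10 persons are
    required for a meaningful cascade.
    """
    if scale < 10:
        raise ValueError(f"scale must be >= 10 persons, got {scale}")
    rng = np.random.default_rng(seed)
    code = f"S{seed % 1000:03d}"
    epi = CountryEpidemiology(
        country_code=code,
        population_size=float(scale),
        segment_overrides=None,
        **{k: float(rng.uniform(lo, hi)) for k, (lo, hi) in _EPI_RANGES.items()},
    )
    reimb = float(rng.choice(_REIMB_LEVELS))
    rp = ResourceParams(
        country_code=code,
        currency="EUR",
        reimb_rate_switched=reimb,
        reimb_rate_other=reimb,
        **{k: float(rng.uniform(lo, hi)) for k, (lo, hi) in _COST_RANGES.items()},
    )
    return epi, rp


@dataclass(frozen=True)
class BruteForceResult:
    """Before/after/savings component costs from the per-patient oracle."""

    before: ComponentCosts
    after: ComponentCosts

    @property
    def savings(self) -> ComponentCosts:
        return self.before - self.after


def _patient_costs(
    segment: int, rp: ResourceParams, sc: SwitchScenario
) -> tuple[dict[str, float], dict[str, float]]:
    """Expected annual (before, after) component costs for one patient."""
    s = sc.rate(segment)
    mu = rp.ae_mitigation if sc.ae_mitigation_override is None else sc.ae_mitigation_override
    before: dict[str, float] = {}
    after: dict[str, float] = {}
    rx = segment in (1, 2)
    attacks = rp.attacks_per_year_rx if rx else rp.attacks_per_year_otc

    # payer drug spend (Pop 1/2 only)
    if rx:
        unit = rp.unit_cost_switched_triptan if segment == 1 else rp.unit_cost_other_triptan
        reimb = rp.reimb_rate_switched if segment == 1 else rp.reimb_rate_other
        before["drug_acquisition"] = attacks * unit * reimb
        if sc.disreimbursement:
            after["drug_acquisition"] = (
                (1 - s) * attacks * rp.unit_cost_other_triptan * rp.reimb_rate_other
            )
        else:
            after["drug_acquisition"] = (1 - s) * attacks * unit * reimb

    # GP visits and the associated time off work (Pop 1/2 only)
    if rx:
        gp = rp.gp_visits_per_year * rp.gp_visit_cost
        before["gp_visits"] = gp
        after["gp_visits"] = gp * (1 - s * rp.unscheduled_visit_fraction)
        toff = (
            rp.gp_visits_per_year
            * rp.gp_visit_workdays_lost
            * rp.gp_visit_during_work_fraction
            * rp.employed_fraction
            * rp.workday_cost
        )
        before["time_off_work"] = toff
        after["time_off_work"] = toff * (1 - s * rp.unscheduled_visit_fraction)

    # emergency room: everyone at baseline; savings for attacks newly covered
    er = attacks * rp.er_prob_per_attack * rp.er_visit_cost
    before["er_visits"] = er
    covered = s * (rp.prob_no_triptan_at_attack if rx else 1.0)
    after["er_visits"] = er * (1 - covered * rp.er_reduction_triptan)

    # cardiovascular events: newly OTC-exposed switchers only
    if segment >= 3:
        after["cv_events"] = (
            s
            * rp.contraindicated_fraction
            * rp.serious_ae_incidence
            * (1 - mu)
            * rp.ae_event_cost
        )

    # medication-overuse headache: newly treated (Pop 4) switchers only
    if segment == 4:
        moh = s * rp.moh_risk * (1 - rp.moh_mitigation)
        after["moh_gp_visits"] = moh * rp.moh_extra_gp_visits * rp.gp_visit_cost
        after["moh_productivity"] = (
            moh
            * rp.moh_extra_attack_days
            * rp.work_hour_attack_fraction
            * rp.employed_fraction
            * (rp.moh_absenteeism + rp.moh_presenteeism * (1 - rp.productivity_level))
            * rp.workday_cost
        )

    # attack-day productivity losses
    absent = rp.absenteeism_rx if rx else rp.absenteeism_otc
    present = rp.presenteeism_rx if rx else rp.presenteeism_otc
    scale = attacks * rp.work_hour_attack_fraction * rp.employed_fraction * rp.workday_cost
    comp = "productivity_rx" if rx else "productivity_otc"
    loss = scale * (absent + present * (1 - rp.productivity_level))
    before[comp] = loss
    saved = (
        scale
        * s
        * (rp.prob_no_triptan_at_attack if rx else 1.0)
        * rp.triptan_productivity_gain
        * (absent * rp.productivity_level + present * (1 - rp.productivity_level))
    )
    after[comp] = loss - saved

    return before, after


def brute_force_costs(
    patients: Iterable[str | Mapping[str, object]],
    rp: ResourceParams,
    sc: SwitchScenario,
) -> BruteForceResult:
    """Sum expected per-patient costs over an explicit patient list.

    Each patient is a segment label ``"pop1"``..``"pop6"`` or a record with a
    ``"segment"`` key holding such a label.
    """
    before_tot = dict.fromkeys(ComponentCosts().__dict__, 0.0)
    after_tot = dict.fromkeys(ComponentCosts().__dict__, 0.0)
    for patient in patients:
        label = patient if isinstance(patient, str) else patient.get("segment")
        if not (
            isinstance(label, str)
            and label.startswith("pop")
            and label[3:] in "123456"
            and len(label) == 4
        ):
            raise ValueError(f"unknown segment label {label!r}")
        before, after = _patient_costs(int(label[3]), rp, sc)
        for comp, value in before.items():
            before_tot[comp] += value
        for comp, value in after.items():
            after_tot[comp] += value
    return BruteForceResult(ComponentCosts(**before_tot), ComponentCosts(**after_tot))


def cohort_labels(counts: Mapping[str, int]) -> list[str]:
    """Expand ``{"pop1": 2, ...}`` into an explicit patient label list."""
    labels: list[str] = []
    for label, n in counts.items():
        labels.extend([label] * int(n))
    return labels
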