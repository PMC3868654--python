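"""Cost engine: the nine cost components before and after the switch.

All components are annual amounts in the country's local currency, computed
at full floating precision (rounding is a display concern).  ``state`` is
``"before"`` (current practice) or ``"after"`` (forecast peak OTC uptake).
Savings are ``before − after``; the adverse-event and medication-overuse
components only exist after the switch, so their savings are negative.

Accrual rules the engine implements:

* Payer drug spend covers reimbursed Rx triptans for Pop 1/Pop 2; switchers'
  OTC purchases leave the payer budget.  Under a disreimbursement policy,
  Pop 1 non-switchers are re-prescribed other Rx triptans.
* The emergency-room baseline applies no triptan-specific reduction; savings
  come from Pop 3-6 switchers (all attacks gain triptan access) and Pop 1/2
  switchers for the fraction of attacks when the drug was previously not at
  hand.  Productivity savings follow the same segment split.
* Cardiovascular adverse events accrue only to newly OTC-exposed switchers
  (Pop 3-6); Pop 1/2 switchers are already triptan-screened.
* Medication-overuse headache accrues to Pop 4 switchers (newly treated);
  Pop 3 switchers are assumed already medicated at no incremental risk.
* Societal totals add the four indirect components to the payer total;
  patients' post-switch out-of-pocket OTC spending is not added back.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Literal

from .cohort import PopulationSegments, derive_segments
from .parameters import CountryEpidemiology, ResourceParams, SwitchScenario

__all__ = [
    "ComponentCosts",
    "BudgetImpactResult",
    "State",
    "COMPONENT_FIELDS",
    "DIRECT_COMPONENTS",
    "INDIRECT_COMPONENTS",
    "drug_acquisition",
    "gp_visit_cost",
    "er_visit_cost",
    "cv_event_cost",
    "moh_gp_cost",
    "time_off_work_cost",
    "productivity_costs",
    "moh_productivity_cost",
    "evaluate_country",
]

State = Literal["before", "after"]

#: payer (third-party payer) components, in reporting order
DIRECT_COMPONENTS = (
    "drug_acquisition",
    "gp_visits",
    "er_visits",
    "cv_events",
    "moh_gp_visits",
)
#: societal-only components
INDIRECT_COMPONENTS = (
    "time_off_work",
    "productivity_rx",
    "productivity_otc",
    "moh_productivity",
)
COMPONENT_FIELDS = DIRECT_COMPONENTS + INDIRECT_COMPONENTS


def _check_state(state: str) -> None:
    if state not in ("before", "after"):
        raise ValueError(f"state must be 'before' or 'after', got {state!r}")


@dataclass(frozen=True)
class ComponentCosts:
    """The nine cost components (local currency/year).

    ``productivity_rx`` covers attack-day productivity losses of Pop 1/Pop 2;
    ``productivity_otc`` those of Pop 3-6.
    """

    drug_acquisition: float = 0.0
    gp_visits: float = 0.0
    er_visits: float = 0.0
    cv_events: float = 0.0
    moh_gp_visits: float = 0.0
    time_off_work: float = 0.0
    productivity_rx: float = 0.0
    productivity_otc: float = 0.0
    moh_productivity: float = 0.0

    @property
    def tpp_total(self) -> float:
        """Third-party-payer total: the five direct components."""
        return sum(getattr(self, f) for f in DIRECT_COMPONENTS)

    @property
    def societal_total(self) -> float:
        """Payer total plus the four indirect components."""
        return self.tpp_total + sum(getattr(self, f) for f in INDIRECT_COMPONENTS)

    def __sub__(self, other: "ComponentCosts") -> "ComponentCosts":
        return ComponentCosts(
            **{
                f.name: getattr(self, f.name) - getattr(other, f.name)
                for f in fields(self)
            }
        )


@dataclass(frozen=True)
class BudgetImpactResult:
    """Before/after/savings component costs and perspective totals for one country."""

    country_code: str
    currency: str
    before: ComponentCosts
    after: ComponentCosts
    savings: ComponentCosts

    @property
    def tpp_before(self) -> float:
        return self.before.tpp_total

    @property
    def tpp_after(self) -> float:
        return self.after.tpp_total

    @property
    def tpp_savings(self) -> float:
        return self.savings.tpp_total

    @property
    def societal_before(self) -> float:
        return self.before.societal_total

    @property
    def societal_after(self) -> float:
        return self.after.societal_total

    @property
    def societal_savings(self) -> float:
        return self.savings.societal_total


# ---------------------------------------------------------------------------
# component operations


def drug_acquisition(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """Payer-borne triptan acquisition cost (patients' OTC spend excluded)."""
    _check_state(state)
    a = rp.attacks_per_year_rx
    cost_sw = a * rp.unit_cost_switched_triptan * rp.reimb_rate_switched
    cost_ot = a * rp.unit_cost_other_triptan * rp.reimb_rate_other
    if state == "before":
        return seg.pop1 * cost_sw + seg.pop2 * cost_ot
    s1, s2 = sc.rate(1), sc.rate(2)
    if sc.disreimbursement:
        # the switched triptan loses Rx status: non-switchers in Pop 1 are
        # re-prescribed other (still reimbursed) triptans
        return seg.pop1 * (1 - s1) * cost_ot + seg.pop2 * (1 - s2) * cost_ot
    return seg.pop1 * (1 - s1) * cost_sw + seg.pop2 * (1 - s2) * cost_ot


def gp_visit_cost(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """GP visit cost for Rx-triptan patients; switchers skip unscheduled visits."""
    _check_state(state)
    per_patient = rp.gp_visits_per_year * rp.gp_visit_cost
    before = seg.rx_triptan * per_patient
    if state == "before":
        return before
    u = rp.unscheduled_visit_fraction
    avoided = sum(seg.pop(i) * per_patient * sc.rate(i) * u for i in (1, 2))
    return before - avoided


def er_visit_cost(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """Emergency-room visit cost across all six segments."""
    _check_state(state)
    attacks = (
        seg.rx_triptan * rp.attacks_per_year_rx
        + seg.otc_or_untreated * rp.attacks_per_year_otc
    )
    before = attacks * rp.er_prob_per_attack * rp.er_visit_cost
    if state == "before":
        return before
    # switchers gain triptan access: Pop 3-6 for all attacks, Pop 1/2 only
    # for attacks when the Rx product was previously unavailable
    newly_covered_attacks = (
        sum(seg.pop(i) * sc.rate(i) for i in (3, 4, 5, 6)) * rp.attacks_per_year_otc
        + (seg.pop1 * sc.rate(1) + seg.pop2 * sc.rate(2))
        * rp.attacks_per_year_rx
        * rp.prob_no_triptan_at_attack
    )
    savings = (
        newly_covered_attacks
        * rp.er_prob_per_attack
        * rp.er_reduction_triptan
        * rp.er_visit_cost
    )
    return before - savings


def _ae_mitigation(rp: ResourceParams, sc: SwitchScenario) -> float:
    return (
        rp.ae_mitigation
        if sc.ae_mitigation_override is None
        else sc.ae_mitigation_override
    )


def cv_event_cost(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """Serious cardiovascular events among newly OTC-exposed switchers (Pop 3-6)."""
    _check_state(state)
    if state == "before":
        return 0.0
    new_otc_users = sum(seg.pop(i) * sc.rate(i) for i in (3, 4, 5, 6))
    return (
        new_otc_users
        * rp.contraindicated_fraction
        * rp.serious_ae_incidence
        * (1 - _ae_mitigation(rp, sc))
        * rp.ae_event_cost
    )


def moh_gp_cost(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """Extra GP visits from medication-overuse headache in Pop 4 switchers."""
    _check_state(state)
    if state == "before":
        return 0.0
    return (
        seg.pop4
        * sc.rate(4)
        * rp.moh_risk
        * (1 - rp.moh_mitigation)
        * rp.moh_extra_gp_visits
        * rp.gp_visit_cost
    )


def time_off_work_cost(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """Work time lost to GP visits (employed patients, visits in work hours)."""
    _check_state(state)
    per_patient = (
        rp.gp_visits_per_year
        * rp.gp_visit_workdays_lost
        * rp.gp_visit_during_work_fraction
        * rp.employed_fraction
        * rp.workday_cost
    )
    before = seg.rx_triptan * per_patient
    if state == "before":
        return before
    u = rp.unscheduled_visit_fraction
    avoided = sum(seg.pop(i) * per_patient * sc.rate(i) * u for i in (1, 2))
    return before - avoided


def _attack_day_weight(rp: ResourceParams, absenteeism: float, presenteeism: float) -> float:
    # lost-workday equivalents per work-hour attack day: full days lost to
    # absenteeism plus the productivity shortfall while present
    return absenteeism + presenteeism * (1 - rp.productivity_level)


def _saved_day_weight(rp: ResourceParams, absenteeism: float, presenteeism: float) -> float:
    # recoverable share of a lost-day equivalent when a triptan becomes
    # available: weights chosen to reproduce the published savings cells
    return absenteeism * rp.productivity_level + presenteeism * (1 - rp.productivity_level)


def productivity_costs(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> tuple[float, float]:
    """Attack-day productivity losses: (Pop 1/2 component, Pop 3-6 component)."""
    _check_state(state)
    scale = rp.work_hour_attack_fraction * rp.employed_fraction * rp.workday_cost
    rx_before = (
        seg.rx_triptan
        * rp.attacks_per_year_rx
        * scale
        * _attack_day_weight(rp, rp.absenteeism_rx, rp.presenteeism_rx)
    )
    otc_before = (
        seg.otc_or_untreated
        * rp.attacks_per_year_otc
        * scale
        * _attack_day_weight(rp, rp.absenteeism_otc, rp.presenteeism_otc)
    )
    if state == "before":
        return rx_before, otc_before
    gain = rp.triptan_productivity_gain
    rx_savings = (
        (seg.pop1 * sc.rate(1) + seg.pop2 * sc.rate(2))
        * rp.attacks_per_year_rx
        * scale
        * rp.prob_no_triptan_at_attack
        * gain
        * _saved_day_weight(rp, rp.absenteeism_rx, rp.presenteeism_rx)
    )
    otc_savings = (
        sum(seg.pop(i) * sc.rate(i) for i in (3, 4, 5, 6))
        * rp.attacks_per_year_otc
        * scale
        * gain
        * _saved_day_weight(rp, rp.absenteeism_otc, rp.presenteeism_otc)
    )
    return rx_before - rx_savings, otc_before - otc_savings


def moh_productivity_cost(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> float:
    """Attack-day productivity losses from medication-overuse headache (Pop 4
    switchers). This component is approximate: the published cells embed an
    unrecoverable weighting and differ from this reconstruction by ~10-14%."""
    _check_state(state)
    if state == "before":
        return 0.0
    return (
        seg.pop4
        * sc.rate(4)
        * rp.moh_risk
        * (1 - rp.moh_mitigation)
        * rp.moh_extra_attack_days
        * rp.work_hour_attack_fraction
        * rp.employed_fraction
        * _attack_day_weight(rp, rp.moh_absenteeism, rp.moh_presenteeism)
        * rp.workday_cost
    )


def component_costs(
    seg: PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
    state: State,
) -> ComponentCosts:
    """Assemble all nine components for one state."""
    prod_rx, prod_otc = productivity_costs(seg, rp, sc, state)
    return ComponentCosts(
        drug_acquisition=drug_acquisition(seg, rp, sc, state),
        gp_visits=gp_visit_cost(seg, rp, sc, state),
        er_visits=er_visit_cost(seg, rp, sc, state),
        cv_events=cv_event_cost(seg, rp, sc, state),
        moh_gp_visits=moh_gp_cost(seg, rp, sc, state),
        time_off_work=time_off_work_cost(seg, rp, sc, state),
        productivity_rx=prod_rx,
        productivity_otc=prod_otc,
        moh_productivity=moh_productivity_cost(seg, rp, sc, state),
    )


def evaluate_country(
    epi: CountryEpidemiology | PopulationSegments,
    rp: ResourceParams,
    sc: SwitchScenario,
) -> BudgetImpactResult:
    """Run the full model for one country under one scenario.

    Accepts either cascade parameters or pre-built segments (toy cohorts).
    """
    seg = epi if isinstance(epi, PopulationSegments) else derive_segments(epi)
    code = rp.country_code if isinstance(epi, PopulationSegments) else epi.country_code
    before = component_costs(seg, rp, sc, "before")
    after = component_costs(seg, rp, sc, "after")
    return BudgetImpactResult(
        country_code=code,
        currency=rp.currency,
        before=before,
        after=after,
        savings=before - after,
    )
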