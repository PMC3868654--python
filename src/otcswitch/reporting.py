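"""Render cascade and before/after/savings tables; display rounding lives here.

Amounts are rounded half-up to whole currency units for display only; all
upstream arithmetic is full precision.  Drug-acquisition cells are rendered
blank for countries where the payer bears no drug cost in any state (zero
reimbursement), mirroring how budget tables conventionally omit empty payer
lines.
"""

from __future__ import annotations

import io
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .cohort import PopulationSegments
from .costs import COMPONENT_FIELDS, BudgetImpactResult
from .scenarios import ScenarioRun

__all__ = ["round_half_up", "render_table4", "render_cascade"]

_COMPONENT_LABELS = {
    "drug_acquisition": "Drug acquisition",
    "gp_visits": "GP visits",
    "er_visits": "ER visits",
    "cv_events": "CV events",
    "moh_gp_visits": "MOH GP visits",
    "time_off_work": "Time off work",
    "productivity_rx": "Productivity loss (Pop1 & Pop2)",
    "productivity_otc": "Productivity loss (Pop3 & Pop4)",
    "moh_productivity": "Additional MOH productivity costs",
}
_STATE_LABELS = {
    "before": "Costs before the switch",
    "after": "Costs after the switch",
    "savings": "Total savings",
}

_CASCADE_ROWS = [
    ("adults_with_migraine", "Adults with migraine population"),
    ("diagnosed", "Diagnosed patients"),
    ("treated", "Treated patients"),
    ("rx_treated", "Adults treated with Rx (w or w/o OTC drugs)"),
    ("pop1", "Pop 1 (diagnosed, treated with Rx triptan to be switched)"),
    ("pop2", "Pop 2 (diagnosed, treated with other Rx triptans)"),
    ("pop3", "Pop 3 (diagnosed, treated with OTC)"),
    ("pop4", "Pop 4 (diagnosed, untreated)"),
    ("pop5", "Pop 5 (undiagnosed, treated with OTC)"),
    ("pop6", "Pop 6 (undiagnosed, not treated)"),
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero upwards (2.5 -> 3)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _check_format(format: str) -> None:
    if format not in ("text", "csv"):
        raise ValueError(f"unsupported format {format!r}; use 'text' or 'csv'")


def _fmt(value: int | str, format: str) -> str:
    if isinstance(value, str):
        return value
    return f"{value:,}" if format == "text" else str(value)


def _result_rows(code: str, res: BudgetImpactResult, format: str) -> list[dict]:
    # blank payer drug cells when the payer never bears drug cost
    blank_drug = (
        res.before.drug_acquisition == 0
        and res.after.drug_acquisition == 0
    )
    rows = []
    for state in ("before", "after", "savings"):
        costs = getattr(res, state)
        row: dict[str, object] = {
            "country": f"{code} ({res.currency} 2010)",
            "row": _STATE_LABELS[state],
        }
        for comp in COMPONENT_FIELDS:
            value = getattr(costs, comp)
            if comp == "drug_acquisition" and blank_drug:
                row[_COMPONENT_LABELS[comp]] = ""
            else:
                row[_COMPONENT_LABELS[comp]] = _fmt(round_half_up(value), format)
        row["TOTAL TPP perspective"] = _fmt(round_half_up(costs.tpp_total), format)
        row["TOTAL Societal perspective"] = _fmt(
            round_half_up(costs.societal_total), format
        )
        rows.append(row)
    return rows


def render_table4(run: ScenarioRun, format: str = "text") -> str:
    """Per-country before/after/savings table plus an EUR-2010 total block."""
    _check_format(format)
    rows = []
    for code, res in run.results.items():
        rows.extend(_result_rows(code, res, format))
    totals = run.totals_eur2010
    for state in ("before", "after", "savings"):
        rows.append(
            {
                "country": "Total (EUR 2010)",
                "row": _STATE_LABELS[state],
                "TOTAL TPP perspective": _fmt(
                    round_half_up(totals["tpp"][state]), format
                ),
                "TOTAL Societal perspective": _fmt(
                    round_half_up(totals["societal"][state]), format
                ),
            }
        )
    frame = pd.DataFrame(rows).fillna("")
    if format == "csv":
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    return frame.to_string(index=False)


def render_cascade(seg: PopulationSegments, format: str = "text") -> str:
    """Cascade levels and segment sizes, rounded to whole persons."""
    _check_format(format)
    frame = pd.DataFrame(
        [
            {"row": label, "persons": _fmt(round_half_up(getattr(seg, attr)), format)}
            for attr, label in _CASCADE_ROWS
        ]
    )
    if format == "csv":
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        return buf.getvalue()
    return frame.to_string(index=False)
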