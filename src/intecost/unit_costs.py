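"""Per-visit unit costs and their fixed/variable input structure.

The headline quantity is the economic unit cost per visit of each service
line: the total annual cost allocated to the service divided by its
annual client-visit count.  Each unit cost decomposes into five input
categories — capital, salaries, other fixed costs (maintenance,
utilities, transport, administration), drugs, and diagnostics/supplies —
and into fixed (capital + salaries + other) versus variable (drugs +
diagnostics/supplies) subtotals.  Money is reported to 2 decimals and
shares to whole percent (half-up); internal arithmetic is unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .allocation import CATEGORIES, AllocationResult
from .cost_model import ServiceOutputs

__all__ = [
    "UnitCostRow",
    "UndefinedUnitCostError",
    "unit_cost",
    "facility_unit_costs",
    "assemble_row",
    "fixed_variable_split",
    "percent",
    "rows_to_long_frame",
    "rows_to_table4",
]


class UndefinedUnitCostError(ValueError):
    """Positive allocated cost with zero recorded visits."""


def percent(fraction: float) -> int:
    """Whole-percent presentation rounding, half-up (0.795 -> 80)."""
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass(frozen=True)
class UnitCostRow:
    """Unit cost per visit for one service, split by input category."""

    service: str
    visits: int
    capital: float
    salaries: float
    other_fixed: float
    drugs: float
    diagnostics_supplies: float
    valuation: str = "economic"
    currency: str = "local"

    @property
    def fixed_subtotal(self) -> float:
        return self.capital + self.salaries + self.other_fixed

    @property
    def variable_subtotal(self) -> float:
        return self.drugs + self.diagnostics_supplies

    @property
    def total(self) -> float:
        return self.fixed_subtotal + self.variable_subtotal

    def component(self, category: str) -> float:
        return {
            "capital": self.capital,
            "salaries": self.salaries,
            "other_fixed": self.other_fixed,
            "drugs": self.drugs,
            "diagnostics_supplies": self.diagnostics_supplies,
        }[category]

    def shares(self) -> dict[str, float]:
        """Each component as a fraction of the total (empty when total=0)."""
        t = self.total
        if t <= 0:
            return {}
        return {c: self.component(c) / t for c in CATEGORIES}

    def scaled(self, factor: float) -> "UnitCostRow":
        return UnitCostRow(
            service=self.service,
            visits=self.visits,
            capital=self.capital * factor,
            salaries=self.salaries * factor,
            other_fixed=self.other_fixed * factor,
            drugs=self.drugs * factor,
            diagnostics_supplies=self.diagnostics_supplies * factor,
            valuation=self.valuation,
            currency=self.currency,
        )


def assemble_row(
    service: str,
    capital: float,
    salaries: float,
    other_fixed: float,
    drugs: float,
    diagnostics_supplies: float,
    visits: int = 0,
    valuation: str = "economic",
    currency: str = "local",
) -> UnitCostRow:
    """Build a unit-cost row directly from per-visit component costs.

    Useful for assembling published per-visit breakdowns (totals, fixed/
    variable subtotals and percentage shares follow by construction).
    """
    return UnitCostRow(
        service=service,
        visits=visits,
        capital=capital,
        salaries=salaries,
        other_fixed=other_fixed,
        drugs=drugs,
        diagnostics_supplies=diagnostics_supplies,
        valuation=valuation,
        currency=currency,
    )


def unit_cost(
    allocated: AllocationResult,
    outputs: ServiceOutputs,
    service: str,
    valuation: str = "economic",
    currency: str = "local",
) -> UnitCostRow:
    """Unit cost per visit for one service from an allocation result.

    Divides each allocated category cost by the service's visit count.
    A service with positive cost but zero visits has no defined unit cost
    and raises :class:`UndefinedUnitCostError` rather than returning an
    infinite value.
    """
    m = allocated.matrix(valuation)
    if service not in m.index:
        raise KeyError(f"service {service!r} not present in allocation result")
    visits = outputs.visit_count(service)
    row = m.loc[service]
    total = float(row.sum())
    if visits <= 0:
        if total > 0:
            raise UndefinedUnitCostError(
                f"service {service}: allocated cost {total:.2f} but zero visits"
            )
        visits = 0
    denom = visits if visits > 0 else 1
    return UnitCostRow(
        service=service,
        visits=visits,
        capital=float(row["capital"]) / denom,
        salaries=float(row["salaries"]) / denom,
        other_fixed=float(row["other_fixed"]) / denom,
        drugs=float(row["drugs"]) / denom,
        diagnostics_supplies=float(row["diagnostics_supplies"]) / denom,
        valuation=valuation,
        currency=currency,
    )


def facility_unit_costs(
    allocated: AllocationResult,
    outputs: ServiceOutputs,
    valuation: str = "economic",
    currency: str = "local",
) -> list[UnitCostRow]:
    """Unit-cost rows for every service that received cost and has visits.

    Services not offered (zero cost everywhere) are excluded rather than
    reported as zero-cost rows.
    """
    rows = []
    m = allocated.matrix(valuation)
    for service in m.index:
        total = float(m.loc[service].sum())
        if total <= 0 and outputs.visit_count(service) <= 0:
            continue
        rows.append(unit_cost(allocated, outputs, service, valuation, currency))
    return rows


def fixed_variable_split(row: UnitCostRow) -> tuple[float, float] | None:
    """(fixed share, variable share) of the per-visit total; None if total=0."""
    t = row.total
    if t <= 0:
        return None
    return (row.fixed_subtotal / t, row.variable_subtotal / t)


def rows_to_long_frame(rows: Sequence[UnitCostRow], facility_id: str = "") -> pd.DataFrame:
    """Long-form table: facility, service, category, per-visit value."""
    recs = []
    for r in rows:
        for cat in CATEGORIES:
            recs.append(
                {
                    "facility": facility_id,
                    "service": r.service,
                    "category": cat,
                    "value": r.component(cat),
                    "valuation": r.valuation,
                    "currency": r.currency,
                    "visits": r.visits,
                }
            )
    return pd.DataFrame(recs)


def rows_to_table4(rows: Sequence[UnitCostRow]) -> pd.DataFrame:
    """Wide per-visit breakdown: input categories x services with subtotals
    and whole-percent shares (published presentation, 2-decimal money)."""
    data: dict[str, list] = {}
    index = [
        "Capital costs",
        "Salaries cost",
        "Other costs",
        "Fixed subtotal",
        "Drugs",
        "Diagnostics",
        "Variable subtotal",
        "Total",
    ]
    for r in rows:
        shares = r.shares()
        t = r.total
        col = [
            round(r.capital, 2),
            round(r.salaries, 2),
            round(r.other_fixed, 2),
            round(r.fixed_subtotal, 2),
            round(r.drugs, 2),
            round(r.diagnostics_supplies, 2),
            round(r.variable_subtotal, 2),
            round(t, 2),
        ]
        pct = (
            [
                percent(shares["capital"]),
                percent(shares["salaries"]),
                percent(shares["other_fixed"]),
                percent(r.fixed_subtotal / t),
                percent(shares["drugs"]),
                percent(shares["diagnostics_supplies"]),
                percent(r.variable_subtotal / t),
                100,
            ]
            if t > 0
            else [""] * 8
        )
        data[r.service] = col
        data[f"{r.service} %"] = pct
    return pd.DataFrame(data, index=index)
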