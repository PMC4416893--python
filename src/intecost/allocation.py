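"""Cost allocation: step-down of overheads, staff time, and direct usage.

Total facility cost reaches the six final service lines by three routes:

1. **Direct (ingredients) assignment.**  Drugs, diagnostics and supplies
   are attributed to individual services from actual usage records; staff
   salaries are apportioned by timesheet-derived service-time fractions;
   capital and recurrent items booked to a final cost centre go straight
   to its service.

2. **Step-down of overhead centres.**  Each overhead centre's accumulated
   cost (its own plus anything received from earlier centres) is
   distributed over all not-yet-processed centres plus the final centres
   using its allocation basis — floor area for utilities/maintenance and
   building capital, staff headcount for management/administration — in a
   single pass: a processed centre never receives cost again.

3. **Ancillary centres** (laboratory, pharmacy) are processed after all
   overheads and distribute to final services by their shares of recorded
   resource usage.

Input categories are preserved through every allocation step (allocated
overhead rent is still an "other fixed" cost at the service level), so
per-visit input breakdowns remain meaningful after allocation.  The
whole procedure conserves cost: matrix total + unallocated = total input,
for both economic and financial valuations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annualization import AnnualizationPolicy, AnnualizedCost, annualize_item
from .cost_model import (
    CostCentre,
    FacilityLedger,
    ServiceOutputs,
    StaffTimeRecord,
    UsageRecord,
)

__all__ = [
    "CATEGORIES",
    "SUBCATEGORY_TO_CATEGORY",
    "AllocationBasis",
    "AllocationStep",
    "AllocationResult",
    "DegenerateBasisError",
    "allocation_shares",
    "allocate_salaries",
    "allocate_variable",
    "step_down",
    "audit_to_frame",
]

#: Report-level input categories (the five-way breakdown used per visit).
CATEGORIES = ("capital", "salaries", "other_fixed", "drugs", "diagnostics_supplies")

FIXED_CATEGORIES = ("capital", "salaries", "other_fixed")
VARIABLE_CATEGORIES = ("drugs", "diagnostics_supplies")

#: Ledger subcategory -> report category.  Supplies fold into the
#: diagnostics column at report level; a long-form report keeps them apart.
SUBCATEGORY_TO_CATEGORY = {
    "building": "capital",
    "equipment": "capital",
    "furniture": "capital",
    "training": "capital",
    "salary": "salaries",
    "building_maintenance": "other_fixed",
    "utilities": "other_fixed",
    "transport": "other_fixed",
    "admin_other": "other_fixed",
    "drugs": "drugs",
    "diagnostics": "diagnostics_supplies",
    "supplies": "diagnostics_supplies",
}

#: Default allocation basis per ledger subcategory: space-driven costs by
#: floor area, administration (and transport) by staff headcount, salaries
#: by timesheet fractions, variable inputs by recorded usage.
DEFAULT_BASIS_BY_SUBCATEGORY = {
    "building": "floor_area",
    "equipment": "floor_area",
    "furniture": "floor_area",
    "training": "staff_count",
    "utilities": "floor_area",
    "building_maintenance": "floor_area",
    "admin_other": "staff_count",
    "transport": "staff_count",
    "salary": "staff_count",
    "drugs": "direct_usage",
    "diagnostics": "direct_usage",
    "supplies": "direct_usage",
}

BASIS_KINDS = ("floor_area", "staff_count", "staff_time_fraction", "direct_usage", "visit_share")

#: Synthetic overhead pool receiving non-service staff time from final centres.
NONSERVICE_POOL = "__nonservice__"


class DegenerateBasisError(ValueError):
    """Every target has a zero basis measurement for a non-empty source pool."""


@dataclass(frozen=True)
class AllocationBasis:
    """An allocation basis and the ledger subcategories it applies to."""

    basis_kind: str
    applies_to: frozenset = frozenset()


@dataclass(frozen=True)
class AllocationStep:
    """One audited transfer: source centre -> target, by basis and share."""

    step: int
    source: str
    basis: str
    target: str
    category: str
    share: float
    amount_economic: float
    amount_financial: float


@dataclass
class AllocationResult:
    """Service x input-category cost matrix after all allocation steps."""

    economic: pd.DataFrame
    financial: pd.DataFrame
    unallocated_economic: float
    unallocated_financial: float
    total_input_economic: float
    total_input_financial: float
    audit_trail: list[AllocationStep] = field(default_factory=list)

    def matrix(self, valuation: str = "economic") -> pd.DataFrame:
        if valuation not in {"economic", "financial"}:
            raise ValueError(f"valuation must be economic|financial, got {valuation!r}")
        return self.economic if valuation == "economic" else self.financial


def audit_to_frame(result: AllocationResult) -> pd.DataFrame:
    """Audit trail as a DataFrame (step, source, basis, target, share, amounts)."""
    return pd.DataFrame(
        [
            {
                "step": s.step,
                "source": s.source,
                "basis": s.basis,
                "target": s.target,
                "category": s.category,
                "share": s.share,
                "amount_economic": s.amount_economic,
                "amount_financial": s.amount_financial,
            }
            for s in result.audit_trail
        ]
    )


# --------------------------------------------------------------------------
# Allocation shares
# --------------------------------------------------------------------------


def _basis_measurement(
    basis_kind: str,
    target: CostCentre,
    staff_time: Sequence[StaffTimeRecord],
    usage: Sequence[UsageRecord],
    outputs: ServiceOutputs | None,
) -> float:
    if basis_kind == "floor_area":
        return float(target.floor_area)
    if basis_kind == "staff_count":
        return float(target.staff_count)
    if basis_kind == "staff_time_fraction":
        if not target.service:
            return 0.0
        return float(
            sum(st.fraction_by_service.get(target.service, 0.0) for st in staff_time)
        )
    if basis_kind == "direct_usage":
        if not target.service:
            return 0.0
        return float(
            sum(u.annual_cost_economic for u in usage if u.service == target.service)
        )
    if basis_kind == "visit_share":
        if not target.service or outputs is None:
            return 0.0
        return float(outputs.visit_count(target.service))
    raise ValueError(f"unknown basis kind {basis_kind!r}; valid: {BASIS_KINDS}")


def allocation_shares(
    basis_kind: str,
    source: CostCentre | str,
    targets: Sequence[CostCentre],
    staff_time: Sequence[StaffTimeRecord] = (),
    usage: Sequence[UsageRecord] = (),
    outputs: ServiceOutputs | None = None,
) -> dict[str, float]:
    """Fractional shares of a source centre's cost over target centres.

    Shares are proportional to the basis measurement of each target and
    sum to exactly 1: the last positive share is set by complement so no
    rounding residue is lost.  Raises :class:`DegenerateBasisError` when
    every measurement is zero.
    """
    source_id = source.centre_id if isinstance(source, CostCentre) else source
    meas = [
        _basis_measurement(basis_kind, t, staff_time, usage, outputs) for t in targets
    ]
    total = sum(meas)
    if total <= 0:
        raise DegenerateBasisError(
            f"centre {source_id}: all {basis_kind} measurements are zero over "
            f"targets {[t.centre_id for t in targets]}"
        )
    shares = {t.centre_id: m / total for t, m in zip(targets, meas)}
    positive = [t.centre_id for t, m in zip(targets, meas) if m > 0]
    last = positive[-1]
    shares[last] = 1.0 - sum(v for k, v in shares.items() if k != last)
    return shares


# --------------------------------------------------------------------------
# Direct allocation of salaries and variable inputs
# --------------------------------------------------------------------------


def allocate_salaries(
    staff_time: Sequence[StaffTimeRecord],
) -> tuple[dict[str, float], dict[str, float]]:
    """Apportion staff salaries to services by timesheet fractions.

    Returns ``(service_costs, residual_by_centre)``: for each staff
    member, salary x fraction goes to each service; the remainder
    ``(1 - sum of fractions) x salary`` is non-service time booked to the
    staff member's own cost centre, to join the overhead pool.
    """
    service_costs: dict[str, float] = {}
    residual: dict[str, float] = {}
    for st in staff_time:
        used = 0.0
        for svc, f in st.fraction_by_service.items():
            amt = st.annual_salary * f
            service_costs[svc] = service_costs.get(svc, 0.0) + amt
            used += f
        rem = (1.0 - used) * st.annual_salary
        if rem > 1e-12 * max(st.annual_salary, 1.0):
            residual[st.cost_centre] = residual.get(st.cost_centre, 0.0) + rem
    return service_costs, residual


def allocate_variable(
    usage: Sequence[UsageRecord],
) -> dict[tuple[str, str], tuple[float, float]]:
    """Sum usage records by (service, report category).

    Drugs map to the ``drugs`` column; diagnostics and supplies fold into
    ``diagnostics_supplies``.  Values are (economic, financial) pairs.
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for u in usage:
        cat = SUBCATEGORY_TO_CATEGORY[u.subcategory]
        key = (u.service, cat)
        e, f = out.get(key, (0.0, 0.0))
        out[key] = (e + u.annual_cost_economic, f + (u.annual_cost_financial or 0.0))
    return out


# --------------------------------------------------------------------------
# Step-down
# --------------------------------------------------------------------------


class _Pool:
    """Per-centre cost pool keyed by report category (economic, financial)."""

    __slots__ = ("cat",)

    def __init__(self) -> None:
        self.cat: dict[str, list[float]] = {}

    def add(self, category: str, econ: float, fin: float) -> None:
        cell = self.cat.setdefault(category, [0.0, 0.0])
        cell[0] += econ
        cell[1] += fin

    def total_economic(self) -> float:
        return sum(v[0] for v in self.cat.values())

    def is_empty(self) -> bool:
        return all(abs(v[0]) == 0.0 and abs(v[1]) == 0.0 for v in self.cat.values())


def _resolve_centre_basis(
    centre: CostCentre,
    own_subcat_cost: Mapping[str, float],
    basis_override: Mapping[str, str] | None,
) -> str:
    """Basis used to step a centre's accumulated pool down.

    Config override wins; otherwise the basis mapped from the dominant
    subcategory of the centre's own costs; staff_count as a last resort.
    Ancillary centres default to direct_usage shares.
    """
    if basis_override and centre.centre_id in basis_override:
        return basis_override[centre.centre_id]
    if centre.kind == "ancillary":
        return "direct_usage"
    if own_subcat_cost:
        dominant = max(sorted(own_subcat_cost), key=lambda s: own_subcat_cost[s])
        basis = DEFAULT_BASIS_BY_SUBCATEGORY.get(dominant)
        if basis in {"direct_usage", "staff_time_fraction"}:
            # centre-level pools of variable/salary costs without service
            # attribution step down by headcount
            basis = "staff_count" if basis == "staff_time_fraction" else basis
        if basis:
            return basis
    return "staff_count"


def step_down(
    ledger: FacilityLedger,
    annualized_capital: Mapping[str, AnnualizedCost] | None = None,
    *,
    policy: AnnualizationPolicy | None = None,
    ordering: str = "by_cost_desc",
    basis_override: Mapping[str, str] | None = None,
) -> AllocationResult:
    """Allocate all ledger costs down to the final service lines.

    Parameters
    ----------
    ledger
        A validated facility ledger.
    annualized_capital
        Annual cost per capital ``item_id``; computed from ``policy``
        (default 3% discount rate) when not supplied.
    ordering
        ``by_cost_desc`` processes overhead centres largest-first (the
        conventional step-down order); ``declared`` keeps ledger order.
        The chosen order is visible in the audit trail.
    basis_override
        Optional ``centre_id -> basis_kind`` map overriding the inferred
        per-centre basis.
    """
    if ordering not in {"by_cost_desc", "declared"}:
        raise ValueError(f"ordering must be by_cost_desc|declared, got {ordering!r}")
    if policy is None:
        policy = AnnualizationPolicy()
    if annualized_capital is None:
        annualized_capital = {
            it.item_id: annualize_item(it, policy) for it in ledger.capital
        }

    centres = {c.centre_id: c for c in ledger.centres}
    services = [c.service for c in ledger.final_centres() if c.service]
    # cost matrix cells, keyed (service, category) -> [econ, fin]
    cell: dict[tuple[str, str], list[float]] = {
        (s, c): [0.0, 0.0] for s in services for c in CATEGORIES
    }

    def credit(service: str, category: str, econ: float, fin: float) -> None:
        cell[(service, category)][0] += econ
        cell[(service, category)][1] += fin

    pools: dict[str, _Pool] = {cid: _Pool() for cid in centres}
    own_subcat: dict[str, dict[str, float]] = {cid: {} for cid in centres}

    total_e = total_f = 0.0

    # --- own costs into centre pools ------------------------------------
    for it in ledger.capital:
        ann = annualized_capital[it.item_id]
        pools[it.cost_centre].add("capital", ann.economic, ann.financial)
        sc = own_subcat[it.cost_centre]
        sc[it.subcategory] = sc.get(it.subcategory, 0.0) + ann.economic
        total_e += ann.economic
        total_f += ann.financial
    for rt in ledger.recurrent:
        cat = SUBCATEGORY_TO_CATEGORY[rt.subcategory]
        fin = rt.annual_cost_financial or 0.0
        pools[rt.cost_centre].add(cat, rt.annual_cost_economic, fin)
        sc = own_subcat[rt.cost_centre]
        sc[rt.subcategory] = sc.get(rt.subcategory, 0.0) + rt.annual_cost_economic
        total_e += rt.annual_cost_economic
        total_f += fin

    # --- staff salaries: service fractions direct, residual to overhead --
    service_salaries, residual_by_centre = allocate_salaries(ledger.staff_time)
    for svc, amt in service_salaries.items():
        if svc in services:
            credit(svc, "salaries", amt, amt)
        else:  # service without a final centre: keep conservation, park in pool
            residual_by_centre[NONSERVICE_POOL] = (
                residual_by_centre.get(NONSERVICE_POOL, 0.0) + amt
            )
    nonservice_pool = _Pool()
    for cid, amt in residual_by_centre.items():
        if cid == NONSERVICE_POOL or centres.get(cid) is None or centres[cid].kind == "final":
            nonservice_pool.add("salaries", amt, amt)
        else:
            pools[cid].add("salaries", amt, amt)
            own_subcat[cid]["salary"] = own_subcat[cid].get("salary", 0.0) + amt
    total_e += sum(st.annual_salary for st in ledger.staff_time)
    total_f += sum(st.annual_salary for st in ledger.staff_time)

    # --- variable inputs by direct usage ---------------------------------
    for (svc, cat), (e, f) in allocate_variable(ledger.usage).items():
        if svc in services:
            credit(svc, cat, e, f)
        total_e += e
        total_f += f

    # --- final-centre own pools flush straight to their service ----------
    for c in ledger.final_centres():
        p = pools[c.centre_id]
        for cat, (e, f) in p.cat.items():
            credit(c.service, cat, e, f)
        p.cat.clear()

    audit: list[AllocationStep] = []
    step_no = 0

    def distribute(source: CostCentre, pool: _Pool, targets: list[CostCentre]) -> None:
        nonlocal step_no
        if pool.is_empty():
            return
        basis = _resolve_centre_basis(
            source, own_subcat.get(source.centre_id, {}), basis_override
        )
        shares = allocation_shares(
            basis, source, targets, ledger.staff_time, ledger.usage, ledger.outputs
        )
        step_no += 1
        for t in targets:
            sh = shares[t.centre_id]
            if sh == 0.0:
                continue
            for cat, (e, f) in pool.cat.items():
                if t.kind == "final":
                    credit(t.service, cat, e * sh, f * sh)
                else:
                    pools[t.centre_id].add(cat, e * sh, f * sh)
                audit.append(
                    AllocationStep(
                        step_no, source.centre_id, basis, t.centre_id, cat, sh, e * sh, f * sh
                    )
                )
        pool.cat.clear()

    # --- step-down over overhead centres ---------------------------------
    overheads = [c for c in ledger.centres if c.kind == "overhead"]
    if ordering == "by_cost_desc":
        overheads.sort(key=lambda c: -pools[c.centre_id].total_economic())
    ancillaries = [c for c in ledger.centres if c.kind == "ancillary"]
    finals = ledger.final_centres()

    remaining = list(overheads)
    while remaining:
        src = remaining.pop(0)
        distribute(src, pools[src.centre_id], remaining + ancillaries + finals)

    # non-service staff time from final centres: facility overhead pool,
    # spread over final centres by headcount
    if not nonservice_pool.is_empty():
        virtual = CostCentre(NONSERVICE_POOL, "overhead")
        basis = (basis_override or {}).get(NONSERVICE_POOL, "staff_count")
        shares = allocation_shares(
            basis, virtual, finals, ledger.staff_time, ledger.usage, ledger.outputs
        )
        step_no += 1
        for t in finals:
            sh = shares[t.centre_id]
            if sh == 0.0:
                continue
            for cat, (e, f) in nonservice_pool.cat.items():
                credit(t.service, cat, e * sh, f * sh)
                audit.append(
                    AllocationStep(
                        step_no, NONSERVICE_POOL, basis, t.centre_id, cat, sh, e * sh, f * sh
                    )
                )
        nonservice_pool.cat.clear()

    # --- ancillary centres to final services ------------------------------
    for anc in ancillaries:
        distribute(anc, pools[anc.centre_id], finals)

    econ = pd.DataFrame(
        {cat: [cell[(s, cat)][0] for s in services] for cat in CATEGORIES}, index=services
    )
    fin = pd.DataFrame(
        {cat: [cell[(s, cat)][1] for s in services] for cat in CATEGORIES}, index=services
    )
    return AllocationResult(
        economic=econ,
        financial=fin,
        unallocated_economic=total_e - float(econ.to_numpy().sum()),
        unallocated_financial=total_f - float(fin.to_numpy().sum()),
        total_input_economic=total_e,
        total_input_financial=total_f,
        audit_trail=audit,
    )
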