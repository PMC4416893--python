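"""Domain types, ledger schema, validation and delimited-text I/O.

A facility "ledger" collects everything that was costed for one facility
(or, for hospitals, its MCH-FP/HIV departments) during one fiscal year:

* capital items (buildings, equipment, furniture, training investments),
* recurrent expenditures (salaries, drugs, diagnostics, supplies,
  maintenance, utilities, transport, administration),
* the cost-centre structure (overhead / ancillary / final service centres),
* staff rosters with timesheet-derived service-time fractions,
* drug/diagnostic usage records attributed to individual services, and
* annual client-visit counts per service line.

Ledgers are stored as a directory bundle of comma-delimited tables
(``meta.csv``, ``centres.csv``, ``capital.csv``, ``recurrent.csv``,
``staff_time.csv``, ``usage.csv``, ``outputs.csv``), one file per entity
type, so that study data stay normalized and diffable.

Economic and financial valuations are carried in parallel: economic cost
values every resource consumed (donated goods included), financial cost
only actual monetary outlays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger("intecost")

__all__ = [
    "SERVICE_CODES",
    "ServiceLine",
    "default_service_registry",
    "FacilityMeta",
    "CapitalItem",
    "RecurrentItem",
    "CostCentre",
    "StaffTimeRecord",
    "UsageRecord",
    "ServiceOutputs",
    "FacilityLedger",
    "LedgerSchemaError",
    "LedgerValueError",
    "ParameterError",
    "read_ledger",
    "write_ledger",
    "read_study",
    "validate_ledger",
    "impute_visits_from_dispensing",
]

# --------------------------------------------------------------------------
# Controlled vocabularies
# --------------------------------------------------------------------------

#: The six service lines costed by the study design.
SERVICE_CODES = ("CaCx", "FP", "PNC", "HCT", "STI", "HIVTx")

OWNERSHIP = frozenset({"public", "NGO"})
LEVELS = frozenset(
    {
        "hospital",
        "district_hospital",
        "subdistrict_hospital",
        "health_centre",
        "public_health_unit",
        "SRH_clinic",
    }
)
#: Facility levels at which costing may legitimately cover departments only.
HOSPITAL_LEVELS = frozenset({"hospital", "district_hospital", "subdistrict_hospital"})
LOCATIONS = frozenset({"urban", "rural"})
MODELS = frozenset({"FP", "PNC", "SRH"})
SCOPES = frozenset({"whole_facility", "departments_only"})

CAPITAL_SUBCATEGORIES = frozenset({"building", "equipment", "furniture", "training"})
RECURRENT_SUBCATEGORIES = frozenset(
    {
        "salary",
        "drugs",
        "diagnostics",
        "supplies",
        "building_maintenance",
        "utilities",
        "transport",
        "admin_other",
    }
)
USAGE_SUBCATEGORIES = frozenset({"drugs", "diagnostics", "supplies"})
CENTRE_KINDS = frozenset({"overhead", "ancillary", "final"})
OUTPUT_SOURCES = frozenset({"register", "imputed"})


class LedgerSchemaError(ValueError):
    """A ledger bundle violates the documented schema (missing column/file)."""


class LedgerValueError(ValueError):
    """A ledger table contains an unparseable or invalid value."""


class ParameterError(ValueError):
    """An operation was called with an out-of-domain parameter."""


@dataclass(frozen=True)
class ServiceLine:
    """One final service line (e.g. FP = family planning)."""

    code: str
    description: str = ""


_DEFAULT_DESCRIPTIONS = {
    "CaCx": "Cervical cancer screening",
    "FP": "Family planning",
    "PNC": "Postnatal care",
    "HCT": "HIV counselling and testing",
    "STI": "Screening and treatment of sexually transmitted infections",
    "HIVTx": "HIV treatment and care",
}


def default_service_registry() -> dict[str, ServiceLine]:
    """Registry of the six default service lines, keyed by code.

    The registry is extensible (add entries before validating a ledger)
    but codes must stay unique; unknown codes in data are hard errors.
    """
    return {c: ServiceLine(c, _DEFAULT_DESCRIPTIONS[c]) for c in SERVICE_CODES}


# --------------------------------------------------------------------------
# Entity types
# --------------------------------------------------------------------------


@dataclass
class FacilityMeta:
    facility_id: str
    country: str
    ownership: str
    level: str
    location: str
    model: str
    costing_scope: str = "whole_facility"
    period: str = "2010/11"


@dataclass
class CapitalItem:
    """One capital resource line.

    ``replacement_value`` is the current replacement value in local
    currency; for buildings it is the *annual* rental-equivalent value
    (already an annual cost).  ``useful_life`` may be left ``None`` to use
    the policy default for the subcategory.  Donated goods carry a
    positive economic value with ``financial_outlay = 0``.
    """

    item_id: str
    subcategory: str
    replacement_value: float
    cost_centre: str
    useful_life: float | None = None
    financial_outlay: float | None = None
    donated: bool = False
    quantity: int = 1

    def __post_init__(self) -> None:
        if self.financial_outlay is None:
            self.financial_outlay = 0.0 if self.donated else self.replacement_value


@dataclass
class RecurrentItem:
    item_id: str
    subcategory: str
    annual_cost_economic: float
    cost_centre: str
    annual_cost_financial: float | None = None

    def __post_init__(self) -> None:
        if self.annual_cost_financial is None:
            self.annual_cost_financial = self.annual_cost_economic


@dataclass
class CostCentre:
    centre_id: str
    kind: str
    service: str | None = None
    floor_area: float = 0.0
    staff_count: float = 0.0


@dataclass
class StaffTimeRecord:
    """One staff member with timesheet-derived service-time fractions.

    Fractions may sum to less than one; the remainder is time spent on
    activities outside the costed service lines and is routed to the
    facility overhead pool during allocation.
    """

    staff_id: str
    cost_centre: str
    annual_salary: float
    fraction_by_service: dict[str, float] = field(default_factory=dict)


@dataclass
class UsageRecord:
    """Drug/diagnostic/supply consumption attributed to one service."""

    item_id: str
    subcategory: str
    service: str
    annual_cost_economic: float
    annual_cost_financial: float | None = None

    def __post_init__(self) -> None:
        if self.annual_cost_financial is None:
            self.annual_cost_financial = self.annual_cost_economic


@dataclass
class ServiceOutputs:
    """Annual client-visit counts per service line."""

    visits: dict[str, int] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)  # register | imputed

    def visit_count(self, service: str) -> int:
        return int(self.visits.get(service, 0))


@dataclass
class FacilityLedger:
    meta: FacilityMeta
    centres: list[CostCentre] = field(default_factory=list)
    capital: list[CapitalItem] = field(default_factory=list)
    recurrent: list[RecurrentItem] = field(default_factory=list)
    staff_time: list[StaffTimeRecord] = field(default_factory=list)
    usage: list[UsageRecord] = field(default_factory=list)
    outputs: ServiceOutputs = field(default_factory=ServiceOutputs)

    def centre(self, centre_id: str) -> CostCentre:
        for c in self.centres:
            if c.centre_id == centre_id:
                return c
        raise KeyError(centre_id)

    def final_centres(self) -> list[CostCentre]:
        return [c for c in self.centres if c.kind == "final"]

    def services_offered(self) -> list[str]:
        return [c.service for c in self.final_centres() if c.service]


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

_FRACTION_TOL = 1e-9


def validate_ledger(
    ledger: FacilityLedger,
    registry: Mapping[str, ServiceLine] | None = None,
) -> list[str]:
    """Check every type invariant; return human-readable violations.

    An empty list means the ledger may enter the pipeline.  Violations are
    data, not exceptions: each names the offending entity and rule.
    """
    registry = registry if registry is not None else default_service_registry()
    v: list[str] = []
    meta = ledger.meta

    if meta.ownership not in OWNERSHIP:
        v.append(f"meta {meta.facility_id}: ownership {meta.ownership!r} not in {sorted(OWNERSHIP)}")
    if meta.level not in LEVELS:
        v.append(f"meta {meta.facility_id}: level {meta.level!r} not in {sorted(LEVELS)}")
    if meta.location not in LOCATIONS:
        v.append(f"meta {meta.facility_id}: location {meta.location!r} not in {sorted(LOCATIONS)}")
    if meta.model not in MODELS:
        v.append(f"meta {meta.facility_id}: model {meta.model!r} not in {sorted(MODELS)}")
    if meta.costing_scope not in SCOPES:
        v.append(f"meta {meta.facility_id}: costing_scope {meta.costing_scope!r} invalid")
    elif meta.costing_scope == "departments_only" and meta.level not in HOSPITAL_LEVELS:
        v.append(
            f"meta {meta.facility_id}: costing_scope=departments_only is only "
            f"permitted for hospital levels, not {meta.level!r}"
        )

    centre_ids = [c.centre_id for c in ledger.centres]
    dupes = {c for c in centre_ids if centre_ids.count(c) > 1}
    for d in sorted(dupes):
        v.append(f"centre {d}: centre_id duplicated")
    known_centres = set(centre_ids)

    n_final = 0
    for c in ledger.centres:
        if c.kind not in CENTRE_KINDS:
            v.append(f"centre {c.centre_id}: kind {c.kind!r} not in {sorted(CENTRE_KINDS)}")
        if c.kind == "final":
            n_final += 1
            if not c.service:
                v.append(f"centre {c.centre_id}: final centre must name a service")
            elif c.service not in registry:
                v.append(
                    f"centre {c.centre_id}: unknown service {c.service!r}; "
                    f"valid codes: {sorted(registry)}"
                )
        elif c.service:
            v.append(f"centre {c.centre_id}: only final centres carry a service")
        if c.floor_area < 0:
            v.append(f"centre {c.centre_id}: floor_area must be >= 0")
        if c.staff_count < 0:
            v.append(f"centre {c.centre_id}: staff_count must be >= 0")
    if n_final == 0:
        v.append(f"ledger {meta.facility_id}: at least one final cost centre is required")

    for it in ledger.capital:
        if it.subcategory not in CAPITAL_SUBCATEGORIES:
            v.append(f"capital {it.item_id}: subcategory {it.subcategory!r} invalid")
        if it.replacement_value < 0:
            v.append(f"capital {it.item_id}: replacement_value must be >= 0")
        if it.useful_life is not None and it.useful_life <= 0:
            v.append(f"capital {it.item_id}: useful_life must be > 0")
        if it.financial_outlay is not None and it.financial_outlay < 0:
            v.append(f"capital {it.item_id}: financial_outlay must be >= 0")
        if it.donated and it.financial_outlay:
            v.append(f"capital {it.item_id}: donated items must have financial_outlay = 0")
        if it.quantity < 1:
            v.append(f"capital {it.item_id}: quantity must be >= 1")
        if it.cost_centre not in known_centres:
            v.append(f"capital {it.item_id}: cost_centre {it.cost_centre!r} is not declared")

    for rt in ledger.recurrent:
        if rt.subcategory not in RECURRENT_SUBCATEGORIES:
            v.append(f"recurrent {rt.item_id}: subcategory {rt.subcategory!r} invalid")
        if rt.annual_cost_economic < 0 or (rt.annual_cost_financial or 0) < 0:
            v.append(f"recurrent {rt.item_id}: annual costs must be >= 0")
        if rt.cost_centre not in known_centres:
            v.append(f"recurrent {rt.item_id}: cost_centre {rt.cost_centre!r} is not declared")

    for st in ledger.staff_time:
        if st.annual_salary < 0:
            v.append(f"staff {st.staff_id}: annual_salary must be >= 0")
        if st.cost_centre not in known_centres:
            v.append(f"staff {st.staff_id}: cost_centre {st.cost_centre!r} is not declared")
        total = 0.0
        for svc, f in st.fraction_by_service.items():
            if svc not in registry:
                v.append(
                    f"staff {st.staff_id}: unknown service {svc!r}; valid codes: {sorted(registry)}"
                )
            if not 0.0 <= f <= 1.0:
                v.append(f"staff {st.staff_id}: fraction for {svc} must be in [0, 1]")
            total += f
        if total > 1.0 + _FRACTION_TOL:
            v.append(f"staff {st.staff_id}: service fractions sum to {total:.6g} > 1")

    for u in ledger.usage:
        if u.subcategory not in USAGE_SUBCATEGORIES:
            v.append(f"usage {u.item_id}: subcategory {u.subcategory!r} invalid")
        if u.service not in registry:
            v.append(
                f"usage {u.item_id}: unknown service {u.service!r}; valid codes: {sorted(registry)}"
            )
        if u.annual_cost_economic < 0 or (u.annual_cost_financial or 0) < 0:
            v.append(f"usage {u.item_id}: annual costs must be >= 0")

    for svc, n in ledger.outputs.visits.items():
        if svc not in registry:
            v.append(f"outputs: unknown service {svc!r}; valid codes: {sorted(registry)}")
        if n < 0:
            v.append(f"outputs {svc}: visit count must be >= 0")
    for svc, src in ledger.outputs.source.items():
        if src not in OUTPUT_SOURCES:
            v.append(f"outputs {svc}: source {src!r} not in {sorted(OUTPUT_SOURCES)}")

    return v


# --------------------------------------------------------------------------
# Visit imputation
# --------------------------------------------------------------------------


def impute_visits_from_dispensing(dispensed_units: float, units_per_visit: float) -> int:
    """Estimate visit counts from drug dispensing records.

    Where client registers were missing, visits are imputed as dispensed
    units divided by the average units per consultation visit, rounded
    half-to-even (unbiased over many ledgers).  The caller should record
    ``source='imputed'`` in :class:`ServiceOutputs`.
    """
    if units_per_visit <= 0:
        raise ParameterError(f"units_per_visit must be > 0, got {units_per_visit}")
    if dispensed_units < 0:
        raise ParameterError("dispensed_units must be >= 0")
    return round(dispensed_units / units_per_visit)


# --------------------------------------------------------------------------
# Bundle I/O
# --------------------------------------------------------------------------

BUNDLE_FILES = (
    "meta.csv",
    "centres.csv",
    "capital.csv",
    "recurrent.csv",
    "staff_time.csv",
    "usage.csv",
    "outputs.csv",
)

_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "meta.csv": ("facility_id", "country", "ownership", "level", "location", "model"),
    "centres.csv": ("centre_id", "kind"),
    "capital.csv": ("item_id", "subcategory", "replacement_value", "cost_centre"),
    "recurrent.csv": ("item_id", "subcategory", "annual_cost_economic", "cost_centre"),
    "staff_time.csv": ("staff_id", "cost_centre", "annual_salary"),
    "usage.csv": ("item_id", "subcategory", "service", "annual_cost_economic"),
    "outputs.csv": ("service", "visits"),
}

_NUMERIC_COLUMNS: dict[str, tuple[str, ...]] = {
    "centres.csv": ("floor_area", "staff_count"),
    "capital.csv": ("replacement_value", "useful_life", "financial_outlay", "quantity"),
    "recurrent.csv": ("annual_cost_economic", "annual_cost_financial"),
    "staff_time.csv": ("annual_salary", "fraction"),
    "usage.csv": ("annual_cost_economic", "annual_cost_financial"),
    "outputs.csv": ("visits",),
}


def _read_table(path: Path, name: str) -> pd.DataFrame:
    fp = path / name
    if not fp.exists():
        raise LedgerSchemaError(f"{path}: missing bundle file {name}")
    df = pd.read_csv(fp, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise LedgerSchemaError(f"{fp}: missing mandatory column(s) {missing}")
    known = set(_REQUIRED_COLUMNS[name]) | set(_NUMERIC_COLUMNS.get(name, ())) | {
        "service",
        "donated",
        "source",
        "costing_scope",
        "period",
        "schema_version",
        "description",
    }
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", fp, unknown)
    for col in _NUMERIC_COLUMNS.get(name, ()):
        if col not in df.columns:
            continue
        for i, raw in enumerate(df[col]):
            if raw == "":
                continue
            try:
                float(raw)
            except ValueError:
                raise LedgerValueError(
                    f"{fp}: row {i}: column {col!r}: cannot parse {raw!r} as a number"
                ) from None
    return df


def _f(raw: str, default: float | None = None) -> float | None:
    return default if raw == "" else float(raw)


def read_ledger(path: str | Path, schema_version: str = "1") -> FacilityLedger:
    """Read one facility bundle (directory of CSV tables) into a ledger.

    Unknown columns are ignored with a logged warning; missing mandatory
    columns and unparseable numbers raise schema / value errors that name
    the column and row.  Unknown service codes are hard errors.
    """
    path = Path(path)
    registry = default_service_registry()

    mdf = _read_table(path, "meta.csv")
    if len(mdf) != 1:
        raise LedgerSchemaError(f"{path}/meta.csv: expected exactly one row, got {len(mdf)}")
    m = mdf.iloc[0]
    meta = FacilityMeta(
        facility_id=m["facility_id"],
        country=m["country"],
        ownership=m["ownership"],
        level=m["level"],
        location=m["location"],
        model=m["model"],
        costing_scope=m.get("costing_scope", "whole_facility") or "whole_facility",
        period=m.get("period", "2010/11") or "2010/11",
    )

    cdf = _read_table(path, "centres.csv")
    centres = [
        CostCentre(
            centre_id=r["centre_id"],
            kind=r["kind"],
            service=(r.get("service", "") or None),
            floor_area=_f(r.get("floor_area", ""), 0.0),
            staff_count=_f(r.get("staff_count", ""), 0.0),
        )
        for _, r in cdf.iterrows()
    ]

    kdf = _read_table(path, "capital.csv")
    capital = [
        CapitalItem(
            item_id=r["item_id"],
            subcategory=r["subcategory"],
            replacement_value=float(r["replacement_value"]),
            cost_centre=r["cost_centre"],
            useful_life=_f(r.get("useful_life", "")),
            financial_outlay=_f(r.get("financial_outlay", "")),
            donated=(r.get("donated", "") or "false").lower() in {"true", "1", "yes"},
            quantity=int(float(r.get("quantity", "") or 1)),
        )
        for _, r in kdf.iterrows()
    ]

    rdf = _read_table(path, "recurrent.csv")
    recurrent = [
        RecurrentItem(
            item_id=r["item_id"],
            subcategory=r["subcategory"],
            annual_cost_economic=float(r["annual_cost_economic"]),
            annual_cost_financial=_f(r.get("annual_cost_financial", "")),
            cost_centre=r["cost_centre"],
        )
        for _, r in rdf.iterrows()
    ]

    sdf = _read_table(path, "staff_time.csv")
    staff: dict[str, StaffTimeRecord] = {}
    for _, r in sdf.iterrows():
        sid = r["staff_id"]
        rec = staff.setdefault(
            sid,
            StaffTimeRecord(
                staff_id=sid,
                cost_centre=r["cost_centre"],
                annual_salary=float(r["annual_salary"]),
            ),
        )
        svc = r.get("service", "")
        if svc:
            if svc not in registry:
                raise LedgerValueError(
                    f"{path}/staff_time.csv: staff {sid}: unknown service {svc!r}; "
                    f"valid codes: {sorted(registry)}"
                )
            rec.fraction_by_service[svc] = float(r.get("fraction", "") or 0.0)

    udf = _read_table(path, "usage.csv")
    usage = []
    for i, r in udf.iterrows():
        if r["service"] not in registry:
            raise LedgerValueError(
                f"{path}/usage.csv: row {i}: unknown service {r['service']!r}; "
                f"valid codes: {sorted(registry)}"
            )
        usage.append(
            UsageRecord(
                item_id=r["item_id"],
                subcategory=r["subcategory"],
                service=r["service"],
                annual_cost_economic=float(r["annual_cost_economic"]),
                annual_cost_financial=_f(r.get("annual_cost_financial", "")),
            )
        )

    odf = _read_table(path, "outputs.csv")
    outputs = ServiceOutputs()
    for i, r in odf.iterrows():
        svc = r["service"]
        if svc not in registry:
            raise LedgerValueError(
                f"{path}/outputs.csv: row {i}: unknown service {svc!r}; "
                f"valid codes: {sorted(registry)}"
            )
        outputs.visits[svc] = int(float(r["visits"]))
        outputs.source[svc] = r.get("source", "") or "register"

    return FacilityLedger(
        meta=meta,
        centres=centres,
        capital=capital,
        recurrent=recurrent,
        staff_time=list(staff.values()),
        usage=usage,
        outputs=outputs,
    )


def write_ledger(ledger: FacilityLedger, path: str | Path) -> Path:
    """Write a ledger as a directory bundle of CSV tables (inverse of read)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    m = ledger.meta
    pd.DataFrame(
        [
            {
                "facility_id": m.facility_id,
                "country": m.country,
                "ownership": m.ownership,
                "level": m.level,
                "location": m.location,
                "model": m.model,
                "costing_scope": m.costing_scope,
                "period": m.period,
            }
        ]
    ).to_csv(path / "meta.csv", index=False)

    pd.DataFrame(
        [
            {
                "centre_id": c.centre_id,
                "kind": c.kind,
                "service": c.service or "",
                "floor_area": c.floor_area,
                "staff_count": c.staff_count,
            }
            for c in ledger.centres
        ],
        columns=["centre_id", "kind", "service", "floor_area", "staff_count"],
    ).to_csv(path / "centres.csv", index=False)

    pd.DataFrame(
        [
            {
                "item_id": it.item_id,
                "subcategory": it.subcategory,
                "replacement_value": it.replacement_value,
                "useful_life": "" if it.useful_life is None else it.useful_life,
                "financial_outlay": it.financial_outlay,
                "donated": str(it.donated).lower(),
                "cost_centre": it.cost_centre,
                "quantity": it.quantity,
            }
            for it in ledger.capital
        ],
        columns=[
            "item_id",
            "subcategory",
            "replacement_value",
            "useful_life",
            "financial_outlay",
            "donated",
            "cost_centre",
            "quantity",
        ],
    ).to_csv(path / "capital.csv", index=False)

    pd.DataFrame(
        [
            {
                "item_id": r.item_id,
                "subcategory": r.subcategory,
                "annual_cost_economic": r.annual_cost_economic,
                "annual_cost_financial": r.annual_cost_financial,
                "cost_centre": r.cost_centre,
            }
            for r in ledger.recurrent
        ],
        columns=[
            "item_id",
            "subcategory",
            "annual_cost_economic",
            "annual_cost_financial",
            "cost_centre",
        ],
    ).to_csv(path / "recurrent.csv", index=False)

    staff_rows = []
    for st in ledger.staff_time:
        if st.fraction_by_service:
            for svc, f in st.fraction_by_service.items():
                staff_rows.append(
                    {
                        "staff_id": st.staff_id,
                        "cost_centre": st.cost_centre,
                        "annual_salary": st.annual_salary,
                        "service": svc,
                        "fraction": f,
                    }
                )
        else:
            staff_rows.append(
                {
                    "staff_id": st.staff_id,
                    "cost_centre": st.cost_centre,
                    "annual_salary": st.annual_salary,
                    "service": "",
                    "fraction": "",
                }
            )
    pd.DataFrame(
        staff_rows, columns=["staff_id", "cost_centre", "annual_salary", "service", "fraction"]
    ).to_csv(path / "staff_time.csv", index=False)

    pd.DataFrame(
        [
            {
                "item_id": u.item_id,
                "subcategory": u.subcategory,
                "service": u.service,
                "annual_cost_economic": u.annual_cost_economic,
                "annual_cost_financial": u.annual_cost_financial,
            }
            for u in ledger.usage
        ],
        columns=[
            "item_id",
            "subcategory",
            "service",
            "annual_cost_economic",
            "annual_cost_financial",
        ],
    ).to_csv(path / "usage.csv", index=False)

    pd.DataFrame(
        [
            {
                "service": svc,
                "visits": n,
                "source": ledger.outputs.source.get(svc, "register"),
            }
            for svc, n in ledger.outputs.visits.items()
        ],
        columns=["service", "visits", "source"],
    ).to_csv(path / "outputs.csv", index=False)

    return path


def read_study(study_dir: str | Path) -> list[FacilityLedger]:
    """Read every facility bundle found under ``study_dir`` (sorted by name)."""
    study_dir = Path(study_dir)
    bundles = sorted(
        d for d in study_dir.iterdir() if d.is_dir() and (d / "meta.csv").exists()
    )
    if not bundles:
        raise LedgerSchemaError(f"{study_dir}: no facility bundles found")
    return [read_ledger(d) for d in bundles]
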