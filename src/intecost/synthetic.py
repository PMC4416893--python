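"""Synthetic multi-facility studies with analytically known unit costs.

The generator emulates the structure of a two-country facility costing
study — public and NGO facilities spanning hospital to health-centre
levels, six service lines, right-skewed (lognormal) visit volumes and
cost levels — and, crucially, builds every ledger *backwards* from chosen
per-visit cost components.  The ground-truth unit costs are therefore
known in closed form by construction, from the generative parameters and
explicit allocation-share arithmetic, never by running the costing
pipeline itself: pipeline output can be checked against them exactly.

Each facility ledger contains:

* one final cost centre per service with floor area and staff headcount,
* an administration overhead centre (allocated by staff headcount) and a
  maintenance/utilities overhead centre (allocated by floor area),
* optionally a pharmacy ancillary centre whose pharmacist salary reaches
  services through recorded-usage shares,
* capital items split over building rent, equipment (partly donated),
  furniture and training, backed out through the annuity factor so the
  annualized value hits the chosen target,
* dedicated staff per service plus a configurable non-service time
  fraction, drug/diagnostic/supply usage records, and visit counts.

Default per-visit cost levels and visit-volume medians follow the
published Kenya-block per-visit component pattern (HIV treatment
drug-heavy, cervical-cancer screening fixed-heavy), with a country cost
multiplier for the higher-cost country.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annualization import AnnualizationPolicy, annualization_factor
from .cost_model import (
    CapitalItem,
    CostCentre,
    FacilityLedger,
    FacilityMeta,
    ParameterError,
    RecurrentItem,
    ServiceOutputs,
    StaffTimeRecord,
    UsageRecord,
    write_ledger,
)

__all__ = [
    "ServiceProfile",
    "StratumSpec",
    "SyntheticStudyParams",
    "GroundTruth",
    "generate_facility",
    "generate_study",
    "paper40_params",
]

CATEGORIES = ("capital", "salaries", "other_fixed", "drugs", "diagnostics_supplies")


@dataclass(frozen=True)
class ServiceProfile:
    """Per-visit cost medians (local currency) and visit-volume median."""

    visit_median: float
    capital: float
    salaries: float
    other_fixed: float
    drugs: float
    diagnostics: float


#: Default per-visit component medians: the published Kenya-block pattern.
DEFAULT_PROFILES: dict[str, ServiceProfile] = {
    "CaCx": ServiceProfile(150, 5.20, 7.80, 0.80, 0.00, 6.20),
    "FP": ServiceProfile(2500, 1.65, 6.94, 0.50, 6.45, 0.99),
    "PNC": ServiceProfile(900, 1.30, 5.75, 0.37, 0.00, 1.86),
    "HCT": ServiceProfile(1200, 1.81, 6.68, 0.97, 0.00, 4.45),
    "STI": ServiceProfile(120, 5.56, 9.74, 6.03, 19.93, 5.10),
    "HIVTx": ServiceProfile(1400, 2.32, 10.19, 0.93, 28.27, 4.63),
}


@dataclass(frozen=True)
class StratumSpec:
    """One sampling stratum of the facility population."""

    country: str
    ownership: str
    level: str
    location: str
    model: str
    count: int = 1


def _paper40_strata() -> list[StratumSpec]:
    k, s = "Kenya-like", "Swaziland-like"
    return [
        StratumSpec(k, "public", "hospital", "urban", "FP", 1),
        StratumSpec(k, "public", "district_hospital", "urban", "FP", 3),
        StratumSpec(k, "public", "district_hospital", "rural", "PNC", 2),
        StratumSpec(k, "public", "subdistrict_hospital", "rural", "FP", 3),
        StratumSpec(k, "public", "subdistrict_hospital", "rural", "PNC", 3),
        StratumSpec(k, "public", "health_centre", "rural", "FP", 5),
        StratumSpec(k, "public", "health_centre", "rural", "PNC", 7),
        StratumSpec(k, "NGO", "SRH_clinic", "urban", "SRH", 6),
        StratumSpec(s, "public", "hospital", "urban", "PNC", 1),
        StratumSpec(s, "public", "health_centre", "rural", "PNC", 5),
        StratumSpec(s, "public", "public_health_unit", "rural", "PNC", 2),
        StratumSpec(s, "NGO", "SRH_clinic", "urban", "SRH", 2),
    ]


@dataclass
class SyntheticStudyParams:
    """Generative parameters for a synthetic costing study.

    ``cost_sigma`` and ``visit_sigma`` are lognormal dispersions (sigma of
    the underlying normal); the defaults give coefficients of variation of
    the same order as published across-facility SD/mean ratios.
    ``overhead_intensity`` is the fraction of each facility's other-fixed
    cost routed through the overhead centres; ``pharmacy_salary_share``
    sizes the ancillary pharmacist salary relative to direct service
    salaries; ``donated_fraction`` is the donated share of equipment value
    (economic cost without financial outlay).
    """

    n_facilities: int = 40
    strata: list[StratumSpec] = field(default_factory=_paper40_strata)
    profiles: dict[str, ServiceProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    country_multipliers: dict[str, float] = field(
        default_factory=lambda: {"Kenya-like": 1.0, "Swaziland-like": 2.0}
    )
    cost_sigma: float = 0.6
    visit_sigma: float = 0.8
    overhead_intensity: float = 0.25
    admin_split: float = 0.6  # of overhead: admin (staff_count) vs maintenance
    pharmacy_salary_share: float = 0.08
    nonservice_fraction: float = 0.0
    donated_fraction: float = 0.15
    discount_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_facilities < 1:
            raise ParameterError("n_facilities must be >= 1")
        if not self.profiles:
            raise ParameterError("at least one service profile is required")
        for frac in (
            self.overhead_intensity,
            self.admin_split,
            self.pharmacy_salary_share,
            self.nonservice_fraction,
            self.donated_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ParameterError(f"fractions must lie in [0, 1], got {frac}")
        if self.cost_sigma < 0 or self.visit_sigma < 0:
            raise ParameterError("dispersions must be >= 0")


def paper40_params(seed: int = 0, **overrides) -> SyntheticStudyParams:
    """The 40-facility, two-country default study configuration."""
    return SyntheticStudyParams(seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Closed-form per-facility cost totals by (service, input category)."""

    facility_id: str
    visits: dict[str, int]
    economic: dict[tuple[str, str], float]
    financial: dict[tuple[str, str], float]

    def total(self, service: str, valuation: str = "economic") -> float:
        src = self.economic if valuation == "economic" else self.financial
        return sum(src[(service, c)] for c in CATEGORIES)

    def unit_cost(self, service: str, category: str | None = None,
                  valuation: str = "economic") -> float:
        v = self.visits[service]
        src = self.economic if valuation == "economic" else self.financial
        if category is None:
            return self.total(service, valuation) / v
        return src[(service, category)] / v

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for (svc, cat), e in self.economic.items():
            recs.append(
                {
                    "facility": self.facility_id,
                    "service": svc,
                    "category": cat,
                    "economic": e,
                    "financial": self.financial[(svc, cat)],
                    "visits": self.visits[svc],
                }
            )
        return pd.DataFrame(recs)


# Capital value split over subcategories (fractions of the capital target).
_CAPITAL_SPLIT = {"building": 0.35, "equipment": 0.40, "furniture": 0.15, "training": 0.10}
_LIFE = {"equipment": 4.0, "furniture": 10.0, "training": 3.0}


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    if median <= 0:
        return 0.0
    return float(median * np.exp(sigma * rng.standard_normal()))


def generate_facility(
    params: SyntheticStudyParams,
    stratum: StratumSpec,
    seed: int | Sequence[int],
    facility_id: str | None = None,
) -> tuple[FacilityLedger, GroundTruth]:
    """Generate one facility ledger and its closed-form ground truth.

    Identical ``params`` and ``seed`` produce byte-identical bundles.
    """
    services = list(params.profiles)
    if not services:
        raise ParameterError(f"stratum {stratum} offers no services")
    rng = np.random.default_rng(seed)
    mult = params.country_multipliers.get(stratum.country, 1.0)
    fid = facility_id or f"{stratum.country[:2].upper()}-{stratum.level}-{rng.integers(10_000):04d}"
    policy = AnnualizationPolicy(discount_rate=params.discount_rate)

    # --- draws ----------------------------------------------------------
    visits = {
        s: max(1, round(_lognormal(rng, params.profiles[s].visit_median, params.visit_sigma)))
        for s in services
    }
    draw = {}  # (service, component) -> per-visit draw
    for s in services:
        p = params.profiles[s]
        for comp, med in (
            ("capital", p.capital),
            ("salaries", p.salaries),
            ("other_fixed", p.other_fixed),
            ("drugs", p.drugs),
            ("diagnostics", p.diagnostics),
        ):
            draw[(s, comp)] = _lognormal(rng, med * mult, params.cost_sigma)

    floor_area = {s: float(rng.uniform(20.0, 100.0)) for s in services}
    staff_count = {s: int(rng.integers(1, 7)) for s in services}
    area_total = sum(floor_area.values())
    staff_total = sum(staff_count.values())
    a_share = {s: floor_area[s] / area_total for s in services}
    q_share = {s: staff_count[s] / staff_total for s in services}

    # --- targets --------------------------------------------------------
    K = {s: draw[(s, "capital")] * visits[s] for s in services}
    direct_sal = {s: draw[(s, "salaries")] * visits[s] for s in services}
    oth = {s: draw[(s, "other_fixed")] * visits[s] for s in services}
    D = {s: draw[(s, "drugs")] * visits[s] for s in services}
    G = {s: draw[(s, "diagnostics")] * visits[s] for s in services}

    phi = params.overhead_intensity
    oth_total = sum(oth.values())
    admin_pool = phi * oth_total * params.admin_split
    maint_pool = phi * oth_total * (1.0 - params.admin_split)
    direct_oth = {s: (1.0 - phi) * oth[s] for s in services}

    usage_total = sum(D.values()) + sum(G.values())
    u_share = (
        {s: (D[s] + G[s]) / usage_total for s in services}
        if usage_total > 0
        else {s: 0.0 for s in services}
    )
    pharm_salary = (
        params.pharmacy_salary_share * sum(direct_sal.values()) if usage_total > 0 else 0.0
    )

    nsf = params.nonservice_fraction
    salary_full = {s: direct_sal[s] / (1.0 - nsf) if nsf < 1 else 0.0 for s in services}
    residual_total = nsf * sum(salary_full.values())

    # --- ledger assembly ------------------------------------------------
    centres = [CostCentre("admin", "overhead"), CostCentre("maintenance", "overhead")]
    for s in services:
        centres.append(
            CostCentre(
                f"svc_{s}", "final", service=s,
                floor_area=floor_area[s], staff_count=staff_count[s],
            )
        )
    capital: list[CapitalItem] = []
    for s in services:
        cc = f"svc_{s}"
        k = K[s]
        capital.append(
            CapitalItem(f"{s}_building", "building", _CAPITAL_SPLIT["building"] * k, cc)
        )
        eq_target = _CAPITAL_SPLIT["equipment"] * k
        af_eq = annualization_factor(params.discount_rate, _LIFE["equipment"])
        don = params.donated_fraction * eq_target
        if don > 0:
            capital.append(
                CapitalItem(
                    f"{s}_equip_donated", "equipment", don * af_eq, cc,
                    useful_life=_LIFE["equipment"], donated=True, financial_outlay=0.0,
                )
            )
        capital.append(
            CapitalItem(
                f"{s}_equip", "equipment", (eq_target - don) * af_eq, cc,
                useful_life=_LIFE["equipment"],
            )
        )
        af_fu = annualization_factor(params.discount_rate, _LIFE["furniture"])
        capital.append(
            CapitalItem(
                f"{s}_furniture", "furniture", _CAPITAL_SPLIT["furniture"] * k * af_fu, cc,
                useful_life=_LIFE["furniture"],
            )
        )
        af_tr = annualization_factor(params.discount_rate, _LIFE["training"])
        capital.append(
            CapitalItem(
                f"{s}_training", "training", _CAPITAL_SPLIT["training"] * k * af_tr, cc,
                useful_life=_LIFE["training"],
            )
        )

    recurrent: list[RecurrentItem] = []
    if admin_pool > 0:
        recurrent.append(RecurrentItem("admin_costs", "admin_other", admin_pool, "admin"))
    if maint_pool > 0:
        recurrent.append(
            RecurrentItem("utilities", "utilities", 0.6 * maint_pool, "maintenance")
        )
        recurrent.append(
            RecurrentItem(
                "building_maint", "building_maintenance", 0.4 * maint_pool, "maintenance"
            )
        )
    for s in services:
        if direct_oth[s] > 0:
            recurrent.append(
                RecurrentItem(f"{s}_transport", "transport", direct_oth[s], f"svc_{s}")
            )

    staff: list[StaffTimeRecord] = []
    for s in services:
        staff.append(
            StaffTimeRecord(
                f"{s}_staff", f"svc_{s}", salary_full[s],
                fraction_by_service={s: 1.0 - nsf} if nsf > 0 else {s: 1.0},
            )
        )
    if pharm_salary > 0:
        centres.append(CostCentre("pharmacy", "ancillary"))
        staff.append(StaffTimeRecord("pharmacist", "pharmacy", pharm_salary))

    usage: list[UsageRecord] = []
    for s in services:
        if D[s] > 0:
            usage.append(UsageRecord(f"{s}_drugs", "drugs", s, D[s]))
        if G[s] > 0:
            usage.append(UsageRecord(f"{s}_diag", "diagnostics", s, 0.7 * G[s]))
            usage.append(UsageRecord(f"{s}_supplies", "supplies", s, 0.3 * G[s]))

    outputs = ServiceOutputs(
        visits=dict(visits), source={s: "register" for s in services}
    )
    meta = FacilityMeta(
        facility_id=fid,
        country=stratum.country,
        ownership=stratum.ownership,
        level=stratum.level,
        location=stratum.location,
        model=stratum.model,
    )
    ledger = FacilityLedger(
        meta=meta, centres=centres, capital=capital, recurrent=recurrent,
        staff_time=staff, usage=usage, outputs=outputs,
    )

    # --- closed-form ground truth ---------------------------------------
    economic: dict[tuple[str, str], float] = {}
    financial: dict[tuple[str, str], float] = {}
    for s in services:
        cap_e = K[s]
        cap_f = K[s] - params.donated_fraction * _CAPITAL_SPLIT["equipment"] * K[s]
        sal = direct_sal[s] + pharm_salary * u_share[s] + residual_total * q_share[s]
        other = direct_oth[s] + admin_pool * q_share[s] + maint_pool * a_share[s]
        economic[(s, "capital")] = cap_e
        financial[(s, "capital")] = cap_f
        economic[(s, "salaries")] = financial[(s, "salaries")] = sal
        economic[(s, "other_fixed")] = financial[(s, "other_fixed")] = other
        economic[(s, "drugs")] = financial[(s, "drugs")] = D[s]
        economic[(s, "diagnostics_supplies")] = financial[(s, "diagnostics_supplies")] = G[s]

    return ledger, GroundTruth(fid, dict(visits), economic, financial)


def generate_study(
    params: SyntheticStudyParams,
    out_dir: str | Path | None = None,
) -> list[tuple[FacilityLedger, GroundTruth]]:
    """Generate a stratified multi-facility study.

    When the stratum counts sum to ``n_facilities`` the design is taken
    as-is (in declared order); otherwise facilities are sampled from the
    strata with probability proportional to their counts.  With
    ``out_dir`` set, facility bundles and a ``ground_truth.csv`` table
    are written to disk.
    """
    if params.n_facilities < 1:
        raise ParameterError("n_facilities must be >= 1")
    counts = sum(st.count for st in params.strata)
    assignment: list[StratumSpec] = []
    if counts == params.n_facilities:
        for st in params.strata:
            assignment.extend([st] * st.count)
    else:
        rng = np.random.default_rng([params.seed, 0xA110C])
        weights = np.array([st.count for st in params.strata], dtype=float)
        idx = rng.choice(len(params.strata), size=params.n_facilities, p=weights / weights.sum())
        assignment = [params.strata[i] for i in idx]

    results = []
    for i, st in enumerate(assignment):
        fid = f"{st.country[:2].upper()}{i:03d}-{st.level}"
        ledger, gt = generate_facility(params, st, seed=[params.seed, i], facility_id=fid)
        results.append((ledger, gt))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frames = []
        for ledger, gt in results:
            write_ledger(ledger, out_dir / ledger.meta.facility_id)
            frames.append(gt.to_frame())
        pd.concat(frames, ignore_index=True).to_csv(out_dir / "ground_truth.csv", index=False)
    return results
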