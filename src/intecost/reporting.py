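"""Multi-facility aggregation and study-level report tables.

Given per-facility unit-cost results, this module produces the standard
study outputs: proportions of visits and costs per service within
facility-type groups, subgroup mean [SD] unit costs (each facility one
unweighted observation; a visit-weighted variant is available behind a
flag), variation summaries, simple two-group comparisons of unit costs,
and an optional bar chart of mean cost per visit by service.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cost_model import FacilityMeta
from .unit_costs import UnitCostRow

logger = logging.getLogger("intecost")

__all__ = [
    "FacilityResult",
    "GROUPINGS",
    "SubgroupSummary",
    "ComparisonResult",
    "proportions_table",
    "subgroup_means",
    "variation_summary",
    "compare_subgroups",
    "plot_mean_costs",
]

#: Supported grouping keys and the FacilityMeta attribute each reads.
GROUPINGS = {
    "country": "country",
    "ownership": "ownership",
    "facility_type": "level",
    "location": "location",
    "model": "model",
}


@dataclass
class FacilityResult:
    """One facility's unit-cost rows plus its metadata."""

    meta: FacilityMeta
    rows: list[UnitCostRow] = field(default_factory=list)

    def row(self, service: str) -> UnitCostRow | None:
        for r in self.rows:
            if r.service == service:
                return r
        return None

    def total_cost(self, service: str) -> float:
        r = self.row(service)
        return 0.0 if r is None else r.total * r.visits

    def visits(self, service: str) -> int:
        r = self.row(service)
        return 0 if r is None else r.visits


@dataclass
class SubgroupSummary:
    """Mean [SD] unit cost per (group, service): the published table shape."""

    grouping: str
    table: pd.DataFrame  # columns: group, service, n, mean, sd, min, max, cv


@dataclass(frozen=True)
class ComparisonResult:
    direction: str  # "a>b", "a<b" or "a=b", by comparison of medians/means
    p_value: float
    statistic: float
    method: str
    n_a: int
    n_b: int


def _group_key(res: FacilityResult, grouping: str) -> str:
    try:
        attr = GROUPINGS[grouping]
    except KeyError:
        raise ValueError(f"grouping must be one of {sorted(GROUPINGS)}, got {grouping!r}")
    return getattr(res.meta, attr)


def proportions_table(
    study: Sequence[FacilityResult], grouping: str = "facility_type"
) -> pd.DataFrame:
    """Share of visits and of total costs per service, within each group.

    Within each group the visit shares sum to 1 and the cost shares sum
    to 1 (before any percent rounding).  Groups with no visits and no
    costs are omitted with a warning.
    """
    services = sorted({r.service for res in study for r in res.rows})
    recs = []
    groups = sorted({_group_key(res, grouping) for res in study})
    for g in groups:
        members = [res for res in study if _group_key(res, grouping) == g]
        tot_visits = sum(res.visits(s) for res in members for s in services)
        tot_costs = sum(res.total_cost(s) for res in members for s in services)
        if tot_visits == 0 and tot_costs == 0:
            logger.warning("proportions_table: group %r has no visits or costs; omitted", g)
            continue
        for s in services:
            v = sum(res.visits(s) for res in members)
            c = sum(res.total_cost(s) for res in members)
            recs.append(
                {
                    "group": g,
                    "service": s,
                    "n_facilities": len(members),
                    "visit_share": v / tot_visits if tot_visits else float("nan"),
                    "cost_share": c / tot_costs if tot_costs else float("nan"),
                }
            )
    return pd.DataFrame(recs)


def subgroup_means(
    study: Sequence[FacilityResult],
    grouping: str = "country",
    weighted: bool = False,
) -> SubgroupSummary:
    """Mean, SD, range and CV of unit costs per (group, service).

    Each facility contributes one observation (its unit cost per visit
    for the service); facilities not offering a service are excluded from
    that service's n.  SD is the sample (ddof=1) standard deviation and
    is reported as NaN when n = 1.  With ``weighted=True`` the mean is
    visit-weighted instead of unweighted.
    """
    services = sorted({r.service for res in study for r in res.rows})
    recs = []
    for g in sorted({_group_key(res, grouping) for res in study}):
        members = [res for res in study if _group_key(res, grouping) == g]
        for s in services:
            obs = [(res.row(s).total, res.row(s).visits) for res in members if res.row(s)]
            if not obs:
                continue
            vals = np.array([v for v, _ in obs], dtype=float)
            w = np.array([n for _, n in obs], dtype=float)
            if weighted and w.sum() > 0:
                mean = float(np.average(vals, weights=w))
            else:
                mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
            recs.append(
                {
                    "group": g,
                    "service": s,
                    "n": len(vals),
                    "mean": mean,
                    "sd": sd,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "cv": sd / mean if mean > 0 and len(vals) > 1 else float("nan"),
                }
            )
    return SubgroupSummary(grouping=grouping, table=pd.DataFrame(recs))


def variation_summary(study: Sequence[FacilityResult]) -> pd.DataFrame:
    """Across-facility variation in cost per visit, per service."""
    services = sorted({r.service for res in study for r in res.rows})
    recs = []
    for s in services:
        vals = np.array(
            [res.row(s).total for res in study if res.row(s)], dtype=float
        )
        if len(vals) == 0:
            continue
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        recs.append(
            {
                "service": s,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": sd,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(recs)


def compare_subgroups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "rank",
) -> ComparisonResult | None:
    """Two-sided two-sample comparison of unit costs between subgroups.

    ``rank`` (default) is the Mann-Whitney U test — unit costs are
    right-skewed, so a rank-based test is the safer default; ``log_t``
    is Welch's t-test on log-transformed costs.  Returns ``None`` with a
    warning when either arm has fewer than 2 observations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        logger.warning("compare_subgroups: need n >= 2 in each arm (got %d, %d)", len(a), len(b))
        return None
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "a>b" if med_a > med_b else ("a<b" if med_a < med_b else "a=b")
    if method == "rank":
        if np.all(a == b[0]) and np.all(b == b[0]):
            # every observation identical: no evidence of difference
            return ComparisonResult("a=b", 1.0, len(a) * len(b) / 2.0, "rank", len(a), len(b))
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(direction, float(min(p, 1.0)), float(stat), "rank", len(a), len(b))
    if method == "log_t":
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("log_t comparison requires strictly positive costs")
        stat, p = stats.ttest_ind(np.log(a), np.log(b), equal_var=False)
        return ComparisonResult(direction, float(p), float(stat), "log_t", len(a), len(b))
    raise ValueError(f"method must be 'rank' or 'log_t', got {method!r}")


def plot_mean_costs(summary: pd.DataFrame, path: str | Path) -> Path:
    """Bar chart of mean cost per visit by service (one bar group per group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    pivot = summary.pivot_table(index="service", columns="group", values="mean") \
        if "group" in summary.columns else summary.set_index("service")[["mean"]]
    ax = pivot.plot.bar(rot=0, figsize=(8, 4))
    ax.set_ylabel("Mean cost per visit")
    ax.set_xlabel("Service")
    fig = ax.get_figure()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
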