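"""Study-level aggregation: share tables, subgroup means, comparisons."""

import itertools
import math

import numpy as np
import pytest

from intecost import (
    FacilityResult,
    assemble_row,
    compare_subgroups,
    proportions_table,
    subgroup_means,
    variation_summary,
)

from conftest import make_meta


def _result(fid, country="Kenya-like", level="health_centre", rows=()):
    return FacilityResult(
        meta=make_meta(facility_id=fid, country=country, level=level), rows=list(rows)
    )


def _row(service, total, visits):
    # put everything in salaries; only the total matters for aggregation
    return assemble_row(service, 0, total, 0, 0, 0, visits=visits)


class TestProportions:
    def test_single_facility_single_service(self):
        study = [_result("A", rows=[_row("FP", 10.0, 100)])]
        t = proportions_table(study)
        assert t.loc[0, "visit_share"] == pytest.approx(1.0)
        assert t.loc[0, "cost_share"] == pytest.approx(1.0)

    def test_equal_costs_split_fifty_fifty(self):
        study = [_result("A", rows=[_row("FP", 5.0, 100), _row("HCT", 10.0, 50)])]
        t = proportions_table(study).set_index("service")
        assert t.loc["FP", "cost_share"] == pytest.approx(0.5)
        assert t.loc["HCT", "cost_share"] == pytest.approx(0.5)

    def test_five_facility_group_matches_hand_sums(self):
        rng = np.random.default_rng(0)
        study = []
        for i in range(5):
            study.append(
                _result(
                    f"F{i}",
                    rows=[
                        _row("FP", float(rng.uniform(5, 20)), int(rng.integers(50, 500))),
                        _row("HCT", float(rng.uniform(5, 20)), int(rng.integers(50, 500))),
                    ],
                )
            )
        t = proportions_table(study).set_index("service")
        tot_v = sum(r.visits for res in study for r in res.rows)
        tot_c = sum(r.total * r.visits for res in study for r in res.rows)
        fp_v = sum(r.visits for res in study for r in res.rows if r.service == "FP")
        fp_c = sum(r.total * r.visits for res in study for r in res.rows if r.service == "FP")
        assert t.loc["FP", "visit_share"] == pytest.approx(fp_v / tot_v, rel=1e-12)
        assert t.loc["FP", "cost_share"] == pytest.approx(fp_c / tot_c, rel=1e-12)

    def test_shares_sum_to_one_within_groups(self):
        study = [
            _result("A", level="hospital", rows=[_row("FP", 3, 10), _row("HCT", 9, 30)]),
            _result("B", rows=[_row("FP", 4, 20)]),
        ]
        t = proportions_table(study, "facility_type")
        for _, grp in t.groupby("group"):
            assert grp["visit_share"].sum() == pytest.approx(1.0, abs=1e-9)
            assert grp["cost_share"].sum() == pytest.approx(1.0, abs=1e-9)


class TestSubgroupMeans:
    def test_identical_facilities_sd_zero(self):
        study = [_result(f"F{i}", rows=[_row("FP", 12.0, 10)]) for i in range(4)]
        t = subgroup_means(study, "country").table
        assert t.loc[0, "sd"] == pytest.approx(0.0)
        assert t.loc[0, "mean"] == pytest.approx(12.0)

    def test_two_point_mean_and_sd(self):
        study = [
            _result("A", rows=[_row("FP", 10.0, 5)]),
            _result("B", rows=[_row("FP", 20.0, 5)]),
        ]
        t = subgroup_means(study, "country").table
        assert t.loc[0, "mean"] == pytest.approx(15.0)
        assert t.loc[0, "sd"] == pytest.approx(math.sqrt(50.0), rel=1e-9)  # 7.071

    def test_n_one_sd_absent(self):
        t = subgroup_means([_result("A", rows=[_row("FP", 10, 5)])], "country").table
        assert math.isnan(t.loc[0, "sd"])

    def test_missing_service_excluded_from_n(self):
        study = [
            _result("A", rows=[_row("FP", 10, 5), _row("HCT", 3, 5)]),
            _result("B", rows=[_row("FP", 20, 5)]),
        ]
        t = subgroup_means(study, "country").table.set_index("service")
        assert t.loc["FP", "n"] == 2
        assert t.loc["HCT", "n"] == 1

    def test_ordering_invariance(self):
        study = [
            _result("A", rows=[_row("FP", 10, 5)]),
            _result("B", rows=[_row("FP", 30, 5)]),
            _result("C", rows=[_row("FP", 20, 5)]),
        ]
        t1 = subgroup_means(study, "country").table
        t2 = subgroup_means(study[::-1], "country").table
        assert t1.equals(t2)

    def test_lognormal_sample_mean_near_analytic(self):
        # n=200 observations from a known lognormal: sample mean within
        # 3 standard errors of exp(mu + sigma^2/2)
        mu, sigma, n = 2.0, 0.5, 200
        rng = np.random.default_rng(42)
        vals = np.exp(rng.normal(mu, sigma, size=n))
        study = [_result(f"F{i}", rows=[_row("FP", float(v), 10)]) for i, v in enumerate(vals)]
        t = subgroup_means(study, "country").table
        analytic = math.exp(mu + sigma**2 / 2)
        se = vals.std(ddof=1) / math.sqrt(n)
        assert abs(t.loc[0, "mean"] - analytic) < 3 * se


class TestComparisons:
    def test_identical_arms_p_one(self):
        res = compare_subgroups([5.0] * 6, [5.0] * 6)
        assert res.p_value == 1.0
        assert res.direction == "a=b"

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.lognormal(2, 0.3, size=20)
        b = a + 100.0
        res = compare_subgroups(a, b)
        assert res.p_value < 0.001
        assert res.direction == "a<b"

    def test_insufficient_n_returns_none(self):
        assert compare_subgroups([1.0], [2.0, 3.0]) is None

    def test_rank_p_matches_exhaustive_permutation_4v4(self):
        """Mann-Whitney exact p equals the brute-force permutation
        distribution of the U statistic on distinct values."""
        a = [1.3, 2.9, 4.1, 8.2]
        b = [2.0, 5.5, 6.7, 9.9]
        res = compare_subgroups(a, b)

        pooled = a + b
        ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

        def u_stat(group_a):
            ra = sum(ranks[v] for v in group_a)
            return ra - len(group_a) * (len(group_a) + 1) / 2

        observed = u_stat(a)
        n = len(pooled)
        dev_obs = abs(observed - len(a) * len(b) / 2)
        count = total = 0
        for combo in itertools.combinations(pooled, 4):
            total += 1
            if abs(u_stat(combo) - len(a) * len(b) / 2) >= dev_obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, rel=1e-9)

    def test_log_t_method(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(2, 0.3, size=15)
        b = rng.lognormal(3, 0.3, size=15)
        res = compare_subgroups(a, b, method="log_t")
        assert res.method == "log_t"
        assert res.p_value < 0.001


def test_variation_summary_min_max_bracket_mean():
    study = [
        _result("A", rows=[_row("FP", 10, 5)]),
        _result("B", rows=[_row("FP", 30, 5)]),
    ]
    t = variation_summary(study).set_index("service")
    assert t.loc["FP", "min"] <= t.loc["FP", "mean"] <= t.loc["FP", "max"]


def test_plot_mean_costs_writes_file(tmp_path):
    from intecost import plot_mean_costs

    study = [
        _result("A", rows=[_row("FP", 10, 5), _row("HCT", 4, 5)]),
        _result("B", rows=[_row("FP", 30, 5)]),
    ]
    t = subgroup_means(study, "country").table
    out = plot_mean_costs(t, tmp_path / "fig.png")
    assert out.exists() and out.stat().st_size > 0
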