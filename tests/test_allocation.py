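"""Step-down allocation against brute-force oracles, plus conservation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from intecost import (
    CostCentre,
    DegenerateBasisError,
    FacilityLedger,
    RecurrentItem,
    ServiceOutputs,
    StaffTimeRecord,
    UsageRecord,
    allocate_salaries,
    allocate_variable,
    allocation_shares,
    paper40_params,
    generate_study,
    step_down,
)
from conftest import make_meta


class TestAllocationShares:
    def test_floor_area_proportionality(self):
        targets = [
            CostCentre("a", "final", service="FP", floor_area=30),
            CostCentre("b", "final", service="HCT", floor_area=10),
        ]
        shares = allocation_shares("floor_area", "src", targets)
        assert shares == {"a": 0.75, "b": 0.25}

    def test_staff_count_symmetry(self):
        targets = [
            CostCentre("a", "final", service="FP", staff_count=2),
            CostCentre("b", "final", service="HCT", staff_count=2),
        ]
        shares = allocation_shares("staff_count", "src", targets)
        assert shares == {"a": 0.5, "b": 0.5}

    def test_staff_time_fraction_basis(self):
        staff = [StaffTimeRecord("s", "c", 100.0, {"FP": 0.5, "HCT": 0.3, "STI": 0.2})]
        targets = [
            CostCentre(f"t{i}", "final", service=s) for i, s in enumerate(["FP", "HCT", "STI"])
        ]
        shares = allocation_shares("staff_time_fraction", "src", targets, staff_time=staff)
        amounts = {t: 100.0 * sh for t, sh in shares.items()}
        assert amounts["t0"] == pytest.approx(50.0)
        assert amounts["t1"] == pytest.approx(30.0)
        assert amounts["t2"] == pytest.approx(20.0)

    def test_degenerate_basis_names_source(self):
        targets = [CostCentre("a", "final", service="FP", floor_area=0)]
        with pytest.raises(DegenerateBasisError, match="lobby"):
            allocation_shares("floor_area", "lobby", targets)

    @given(st.lists(st.floats(0.01, 1000), min_size=2, max_size=6))
    def test_shares_sum_to_exactly_one(self, areas):
        targets = [
            CostCentre(f"c{i}", "final", service="FP", floor_area=a)
            for i, a in enumerate(areas)
        ]
        shares = allocation_shares("floor_area", "src", targets)
        assert sum(shares.values()) == 1.0
        assert all(s >= 0 for s in shares.values())


class TestSalariesAndVariable:
    def test_full_time_single_service(self):
        costs, residual = allocate_salaries([StaffTimeRecord("s", "c", 100.0, {"FP": 1.0})])
        assert costs == {"FP": pytest.approx(100.0)}
        assert residual == {}

    def test_partial_time_leaves_residual(self):
        costs, residual = allocate_salaries(
            [StaffTimeRecord("s", "c", 100.0, {"FP": 0.4, "HCT": 0.4})]
        )
        assert costs["FP"] == pytest.approx(40.0)
        assert costs["HCT"] == pytest.approx(40.0)
        assert residual["c"] == pytest.approx(20.0)

    def test_ten_staff_brute_force_sum(self):
        rng = np.random.default_rng(7)
        services = ["FP", "HCT", "STI"]
        staff = []
        for i in range(10):
            fr = rng.dirichlet([1, 1, 1, 1])  # last entry is non-service time
            staff.append(
                StaffTimeRecord(
                    f"s{i}", "c", float(rng.uniform(100, 1000)),
                    dict(zip(services, map(float, fr[:3]))),
                )
            )
        costs, residual = allocate_salaries(staff)
        for k, svc in enumerate(services):
            oracle = sum(st_.annual_salary * st_.fraction_by_service[svc] for st_ in staff)
            assert costs[svc] == pytest.approx(oracle, rel=1e-12)
        oracle_resid = sum(
            st_.annual_salary * (1 - sum(st_.fraction_by_service.values())) for st_ in staff
        )
        assert residual["c"] == pytest.approx(oracle_resid, rel=1e-10)

    def test_variable_empty(self):
        assert allocate_variable([]) == {}

    def test_variable_sums_by_service(self):
        out = allocate_variable(
            [
                UsageRecord("a", "drugs", "STI", 10.0),
                UsageRecord("b", "drugs", "STI", 5.0),
            ]
        )
        assert out[("STI", "drugs")] == (pytest.approx(15.0), pytest.approx(15.0))

    def test_supplies_fold_into_diagnostics_and_match_groupby_oracle(self):
        rng = np.random.default_rng(3)
        services = ["FP", "HCT", "HIVTx", "STI"]
        subs = ["drugs", "diagnostics", "supplies"]
        records = [
            UsageRecord(
                f"u{i}",
                subs[rng.integers(3)],
                services[rng.integers(4)],
                float(rng.uniform(1, 100)),
            )
            for i in range(20)
        ]
        out = allocate_variable(records)
        for svc in services:
            drugs = sum(r.annual_cost_economic for r in records
                        if r.service == svc and r.subcategory == "drugs")
            diag = sum(r.annual_cost_economic for r in records
                       if r.service == svc and r.subcategory in {"diagnostics", "supplies"})
            if drugs:
                assert out[(svc, "drugs")][0] == pytest.approx(drugs, rel=1e-12)
            if diag:
                assert out[(svc, "diagnostics_supplies")][0] == pytest.approx(diag, rel=1e-12)


def _two_level_ledger(staff_counts=(1, 3)):
    return FacilityLedger(
        meta=make_meta(),
        centres=[
            CostCentre("admin", "overhead"),
            CostCentre("fp", "final", service="FP", staff_count=staff_counts[0]),
            CostCentre("hct", "final", service="HCT", staff_count=staff_counts[1]),
        ],
        recurrent=[RecurrentItem("adm", "admin_other", 100.0, "admin")],
        outputs=ServiceOutputs(visits={"FP": 10, "HCT": 10}),
    )


class TestStepDown:
    def test_no_overheads_is_identity(self, tiny_ledger):
        res = step_down(tiny_ledger)
        m = res.economic
        assert m.loc["FP", "salaries"] == pytest.approx(1000.0)
        assert m.loc["FP", "other_fixed"] == pytest.approx(50.0)
        assert m.loc["FP", "drugs"] == pytest.approx(200.0)
        assert res.unallocated_economic == pytest.approx(0.0, abs=1e-9)

    def test_single_overhead_staff_count_split(self):
        res = step_down(_two_level_ledger())
        assert res.economic.loc["FP", "other_fixed"] == pytest.approx(25.0)
        assert res.economic.loc["HCT", "other_fixed"] == pytest.approx(75.0)

    def test_single_overhead_invariant_to_ordering(self):
        a = step_down(_two_level_ledger(), ordering="by_cost_desc")
        b = step_down(_two_level_ledger(), ordering="declared")
        assert np.allclose(a.economic.to_numpy(), b.economic.to_numpy())

    def test_category_preserved_through_allocation(self):
        res = step_down(_two_level_ledger())
        # overhead admin costs stay in the other_fixed column, never capital
        assert res.economic["capital"].sum() == 0.0
        assert res.economic["other_fixed"].sum() == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_chain_matches_matrix_product_oracle(self, seed):
        """Two overhead centres feeding each other and two finals: the
        implementation must equal an explicit product of allocation
        matrices computed independently from the instance data."""
        rng = np.random.default_rng(seed)
        staff = rng.uniform(1, 10, size=4)   # staff counts: O2, F1, F2 get some
        areas = rng.uniform(5, 50, size=4)
        costs = rng.uniform(10, 500, size=2)  # own cost of O1, O2
        direct = rng.uniform(10, 500, size=2)  # own cost of F1, F2
        centres = [
            CostCentre("o1", "overhead", staff_count=staff[0], floor_area=areas[0]),
            CostCentre("o2", "overhead", staff_count=staff[1], floor_area=areas[1]),
            CostCentre("f1", "final", service="FP", staff_count=staff[2], floor_area=areas[2]),
            CostCentre("f2", "final", service="HCT", staff_count=staff[3], floor_area=areas[3]),
        ]
        ledger = FacilityLedger(
            meta=make_meta(),
            centres=centres,
            recurrent=[
                RecurrentItem("c1", "admin_other", float(costs[0]), "o1"),
                RecurrentItem("c2", "utilities", float(costs[1]), "o2"),
                RecurrentItem("d1", "transport", float(direct[0]), "f1"),
                RecurrentItem("d2", "transport", float(direct[1]), "f2"),
            ],
            outputs=ServiceOutputs(visits={"FP": 1, "HCT": 1}),
        )
        res = step_down(ledger, ordering="declared")

        # oracle: explicit allocation-matrix product over centre order
        # o1 (staff_count basis) -> {o2, f1, f2}; o2 (floor_area) -> {f1, f2}
        v = np.array([costs[0], costs[1], 0.0, 0.0])
        m1 = np.eye(4)
        w = np.array([0.0, staff[1], staff[2], staff[3]])
        m1[0] = w / w.sum()
        m2 = np.eye(4)
        w2 = np.array([0.0, 0.0, areas[2], areas[3]])
        m2[1] = w2 / w2.sum()
        final = v @ m1 @ m2 + np.array([0, 0, direct[0], direct[1]])
        got = res.economic.sum(axis=1)
        assert got["FP"] == pytest.approx(final[2], rel=1e-9)
        assert got["HCT"] == pytest.approx(final[3], rel=1e-9)

    def test_ancillary_distributes_by_usage_shares(self):
        ledger = FacilityLedger(
            meta=make_meta(),
            centres=[
                CostCentre("pharmacy", "ancillary"),
                CostCentre("fp", "final", service="FP", staff_count=1),
                CostCentre("sti", "final", service="STI", staff_count=1),
            ],
            recurrent=[RecurrentItem("ph", "supplies", 100.0, "pharmacy")],
            usage=[
                UsageRecord("u1", "drugs", "FP", 30.0),
                UsageRecord("u2", "drugs", "STI", 70.0),
            ],
            outputs=ServiceOutputs(visits={"FP": 1, "STI": 1}),
        )
        res = step_down(ledger)
        assert res.economic.loc["FP", "diagnostics_supplies"] == pytest.approx(30.0 * 1.0)
        assert res.economic.loc["STI", "diagnostics_supplies"] == pytest.approx(70.0)

    def test_nonservice_staff_time_spreads_by_headcount(self):
        ledger = _two_level_ledger()
        ledger.staff_time = [StaffTimeRecord("s", "fp", 1000.0, {"FP": 0.6})]
        res = step_down(ledger)
        # 600 direct to FP; 400 residual spread 1:3 over fp/hct staff counts
        assert res.economic.loc["FP", "salaries"] == pytest.approx(600 + 400 * 0.25)
        assert res.economic.loc["HCT", "salaries"] == pytest.approx(400 * 0.75)

    def test_degenerate_overhead_basis_raises(self):
        ledger = _two_level_ledger(staff_counts=(0, 0))
        with pytest.raises(DegenerateBasisError, match="admin"):
            step_down(ledger)


class TestConservationAndScaling:
    def test_conservation_over_random_ledgers(self):
        params = paper40_params(seed=19, nonservice_fraction=0.1)
        params.n_facilities = 30
        for ledger, _ in generate_study(params):
            res = step_down(ledger)
            for val in ("economic", "financial"):
                total_in = getattr(res, f"total_input_{val}")
                allocated = float(res.matrix(val).to_numpy().sum())
                unalloc = getattr(res, f"unallocated_{val}")
                assert allocated + unalloc == pytest.approx(total_in, rel=1e-6)
                assert abs(unalloc) <= 1e-6 * max(total_in, 1.0)
                assert (res.matrix(val).to_numpy() >= 0).all()

    @given(st.floats(0.1, 50))
    def test_scaling_inputs_scales_matrix(self, c):
        base = step_down(_two_level_ledger()).economic
        scaled_ledger = _two_level_ledger()
        for r in scaled_ledger.recurrent:
            r.annual_cost_economic *= c
            r.annual_cost_financial *= c
        scaled = step_down(scaled_ledger).economic
        assert np.allclose(scaled.to_numpy(), base.to_numpy() * c, rtol=1e-9)
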