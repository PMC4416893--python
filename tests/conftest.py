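import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from intecost import (
    CapitalItem,
    CostCentre,
    FacilityLedger,
    FacilityMeta,
    RecurrentItem,
    ServiceOutputs,
    StaffTimeRecord,
    UsageRecord,
)


def make_meta(**kw) -> FacilityMeta:
    base = dict(
        facility_id="F1",
        country="Kenya-like",
        ownership="public",
        level="health_centre",
        location="rural",
        model="FP",
    )
    base.update(kw)
    return FacilityMeta(**base)


@pytest.fixture
def tiny_ledger() -> FacilityLedger:
    """One final centre, one capital item, one staff, one usage record."""
    return FacilityLedger(
        meta=make_meta(),
        centres=[CostCentre("fp", "final", service="FP", floor_area=30, staff_count=2)],
        capital=[CapitalItem("bed", "equipment", 400.0, "fp", useful_life=4.0)],
        recurrent=[RecurrentItem("fuel", "transport", 50.0, "fp")],
        staff_time=[StaffTimeRecord("n1", "fp", 1000.0, {"FP": 1.0})],
        usage=[UsageRecord("pills", "drugs", "FP", 200.0)],
        outputs=ServiceOutputs(visits={"FP": 100}, source={"FP": "register"}),
    )


@pytest.fixture
def two_service_ledger() -> FacilityLedger:
    """Two final services under one overhead centre (staff-count basis)."""
    return FacilityLedger(
        meta=make_meta(facility_id="F2"),
        centres=[
            CostCentre("admin", "overhead"),
            CostCentre("fp", "final", service="FP", floor_area=30, staff_count=1),
            CostCentre("hct", "final", service="HCT", floor_area=10, staff_count=3),
        ],
        recurrent=[
            RecurrentItem("adm", "admin_other", 100.0, "admin"),
            RecurrentItem("fp_tr", "transport", 10.0, "fp"),
            RecurrentItem("hct_tr", "transport", 20.0, "hct"),
        ],
        outputs=ServiceOutputs(visits={"FP": 10, "HCT": 20}),
    )
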