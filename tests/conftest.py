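import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drgcost import records as rec
from drgcost import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cc_setup():
    """Synthetic CC tables and code universe shared across tests."""
    return syn.generate_cc_tables(seed=3, n_codes=30)


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-condition cohort (n=5204, seed 0): records, tables,
    universe and the derived analysis frame."""
    config = syn.default_config(n=5204, seed=0)
    table, universe = syn.generate_cc_tables(seed=0, n_codes=config.n_codes)
    records = syn.generate_cohort(config, table, universe)
    frame = rec.cohort_frame(records, table)
    return {
        "config": config,
        "records": records,
        "table": table,
        "universe": universe,
        "frame": frame,
    }


@pytest.fixture()
def simple_cc_table():
    """Tiny hand-built CC table: one MCC code, one CC code, one exclusion."""
    return rec.CCTable(
        mcc_codes=frozenset({"M1", "M2"}),
        cc_codes=frozenset({"C1", "C2"}),
        exclusion={"M1": frozenset({"P9"}), "C1": frozenset({"P9"})},
    )


def make_record(**overrides) -> rec.InpatientRecord:
    base = dict(
        record_id="r1",
        sex="male",
        age=70,
        allergy=False,
        social_insurance=True,
        admission_route="emergency",
        discharge_mode="home",
        admission_year=2019,
        los=8,
        primary_dx="P1",
        secondary_dx=(),
        procedures=(),
        total_cost=1000.0,
        cost_components={c: (1000.0 / 8) for c in rec.COST_COMPONENTS},
    )
    base.update(overrides)
    return rec.InpatientRecord(**base)


@pytest.fixture()
def record_factory():
    return make_record
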