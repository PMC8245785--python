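"""Carbon-budget assembly: C_I, carbon-specific growth, GGE, partitioning."""

import pytest
from hypothesis import given, settings, strategies as st

from kleptocarbon import (
    Treatment,
    carbon_specific_growth,
    gge,
    ingested_carbon,
    partition,
    summarize,
)
from kleptocarbon.budget import assemble
from kleptocarbon.grazing import GrazingResult, Interval
from kleptocarbon.io_formats import RateRecord


def test_ingested_carbon(treatment):
    assert ingested_carbon(100.0, treatment) == pytest.approx(1000.0)
    assert ingested_carbon(0.0, treatment) == 0.0
    fat = Treatment("x", irradiance=40.0, prey_carbon=12.0)
    assert ingested_carbon(100.0, fat) == pytest.approx(1200.0)


def test_carbon_specific_growth():
    assert carbon_specific_growth(0.3, 2000.0) == pytest.approx(600.0)
    assert carbon_specific_growth(0.0, 2000.0) == 0.0
    assert carbon_specific_growth(-0.2, 1000.0) == pytest.approx(-200.0)


def test_gge_values_and_undefined():
    assert gge(600.0, 1000.0) == pytest.approx(0.6)
    assert gge(1000.0, 1000.0) == pytest.approx(1.0)
    assert gge(1100.0, 1000.0) == pytest.approx(1.1)  # never clamped
    assert gge(600.0, 0.0) is None


def test_partition_reference_cases():
    assert partition(100.0, 100.0) == pytest.approx((50.0, 50.0))
    assert partition(0.0, 500.0) == pytest.approx((0.0, 100.0))
    assert partition(500.0, 0.0) == pytest.approx((100.0, 0.0))
    assert partition(0.0, 0.0) is None


@given(p=st.floats(min_value=0.0, max_value=1e6),
       c=st.floats(min_value=0.0, max_value=1e6))
@settings(max_examples=200, derandomize=True)
def test_partition_sums_to_hundred(p, c):
    res = partition(p, c)
    if res is not None:
        photo, ingest = res
        assert photo + ingest == 100.0
        assert 0.0 <= photo <= 100.0


@given(mu_yc=st.floats(min_value=-1e4, max_value=1e4),
       c_i=st.floats(min_value=1e-3, max_value=1e6),
       s=st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=100, derandomize=True)
def test_gge_invariant_to_carbon_unit_rescaling(mu_yc, c_i, s):
    assert gge(s * mu_yc, s * c_i) == pytest.approx(gge(mu_yc, c_i), rel=1e-9)


def _interval(**kw):
    defaults = dict(culture_id="c1", t0=2.0, t1=3.0, N0=15.0, N1=20.0,
                    C0=4e4, C1=3e4, k_control=0.5, treatment_id="I40")
    defaults.update(kw)
    return Interval(**defaults)


def test_assemble_full_record(treatment):
    grazing = GrazingResult(mu_y=0.3, g=0.8, F=0.05, I=500.0)
    rec = assemble(_interval(), grazing, treatment,
                   biovolume=20000.0, p_daily=140.0, chl_cell=65.0)
    assert rec.C_y == pytest.approx(3800.0)
    assert rec.mu_yC == pytest.approx(0.3 * 3800.0)
    assert rec.C_I == pytest.approx(5000.0)
    assert rec.GGE == pytest.approx(1140.0 / 5000.0)
    assert rec.photo_pct == pytest.approx(100 * 140.0 / 5140.0)
    assert rec.P_chl == pytest.approx(140.0 / 65.0)
    assert rec.flags == set()


def test_assemble_missing_uptake_leaves_partition_undefined(treatment):
    grazing = GrazingResult(mu_y=0.3, g=0.8, F=0.05, I=500.0)
    rec = assemble(_interval(), grazing, treatment, biovolume=20000.0)
    assert rec.GGE is not None
    assert rec.photo_pct is None and rec.P_daily is None


def test_assemble_starved_interval(treatment):
    # no prey ingested: budget is all photosynthesis, GGE undefined
    grazing = GrazingResult(mu_y=-0.2, g=0.0, F=0.0, I=0.0)
    rec = assemble(_interval(), grazing, treatment,
                   biovolume=15000.0, p_daily=90.0)
    assert rec.C_I == 0.0
    assert rec.GGE is None and "undefined_rate" in rec.flags
    assert rec.photo_pct == pytest.approx(100.0)


def _rec(tid, day, mu):
    return RateRecord(culture_id=f"{tid}-r", treatment_id=tid,
                      t0=day - 1, t1=day, mu_y=mu)


def test_summarize_identical_triplicates_have_zero_std():
    table = summarize([_rec("I40", 3.0, 0.5) for _ in range(3)])
    row = table[(table.field == "mu_y")].iloc[0]
    assert row["mean"] == pytest.approx(0.5)
    assert row["std"] == 0.0 and row["n"] == 3


def test_summarize_textbook_std():
    recs = [_rec("I40", 3.0, v) for v in (1.0, 2.0, 3.0)]
    row = summarize(recs)[lambda d: d.field == "mu_y"].iloc[0]
    assert row["mean"] == pytest.approx(2.0)
    assert row["std"] == pytest.approx(1.0)


def test_summarize_grouping_cardinality():
    recs = [_rec(f"T{i}", float(d), 0.1 * i) for i in range(3) for d in (3, 4, 5)]
    table = summarize(recs)
    assert len(table[table.field == "mu_y"]) == 9
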