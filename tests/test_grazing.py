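"""Growth and Frost-Heinbokel grazing estimators against closed forms and
a fine-step forward-simulation oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from kleptocarbon import (
    CountObservation,
    GrazingConfig,
    Interval,
    build_intervals,
    clearance_ingestion,
    frost_mean_density,
    grazing_coefficient,
    growth_rate,
)

pos = st.floats(min_value=1.0, max_value=1e6)


# ---------------------------------------------------------------------------
# growth_rate
# ---------------------------------------------------------------------------

def test_growth_rate_reference_values():
    assert growth_rate(100.0, 100.0, 1.0) == 0.0
    assert growth_rate(100.0, 200.0, 1.0) == pytest.approx(math.log(2), rel=1e-12)
    # closed-form exponential trajectory recovers the injected rate
    n1 = 175.0 * math.exp(0.35 * 2.0)
    assert growth_rate(175.0, n1, 2.0) == pytest.approx(0.35, rel=1e-12)


def test_growth_rate_zero_density_is_undefined_not_exception():
    assert growth_rate(0.0, 100.0, 1.0) is None
    assert growth_rate(100.0, 0.0, 1.0) is None
    with pytest.raises(ValueError):
        growth_rate(100.0, 100.0, 0.0)


@given(n0=pos, n1=pos, s=st.floats(min_value=0.01, max_value=100.0))
@settings(max_examples=100, derandomize=True)
def test_growth_rate_antisymmetry_and_scale_invariance(n0, n1, s):
    mu = growth_rate(n0, n1, 1.0)
    assert growth_rate(n1, n0, 1.0) == pytest.approx(-mu, abs=1e-12)
    assert growth_rate(s * n0, s * n1, 1.0) == pytest.approx(mu, abs=1e-9)


# ---------------------------------------------------------------------------
# frost_mean_density
# ---------------------------------------------------------------------------

def test_frost_mean_reference_values():
    assert frost_mean_density(1000.0, 1000.0) == 1000.0
    assert frost_mean_density(1000.0, 2000.0) == pytest.approx(1000.0 / math.log(2), rel=1e-12)
    assert frost_mean_density(2000.0, 1000.0) == pytest.approx(1442.695, rel=1e-6)
    assert frost_mean_density(0.0, 1000.0) is None


@given(a=pos, b=pos)
@settings(max_examples=100, derandomize=True)
def test_frost_mean_bounds_and_time_average(a, b):
    m = frost_mean_density(a, b)
    assert min(a, b) <= m <= max(a, b)
    # equals the time average of the exponential path from a to b over [0, 1]
    r = math.log(b / a)
    avg, _ = quad(lambda t: a * math.exp(r * t), 0.0, 1.0)
    assert m == pytest.approx(avg, rel=1e-7)


# ---------------------------------------------------------------------------
# grazing_coefficient
# ---------------------------------------------------------------------------

def test_grazing_coefficient_reference_values():
    # prey in the grazed culture growing exactly at the control rate
    assert grazing_coefficient(0.5, 1e4, 1e4 * math.exp(0.5), 1.0) == pytest.approx(0.0, abs=1e-12)
    assert grazing_coefficient(0.5, 1e4, 1e4 * math.exp(-0.2), 1.0) == pytest.approx(0.7, rel=1e-12)
    # prey outgrowing the control gives negative g
    assert grazing_coefficient(0.1, 1e4, 1e4 * math.exp(0.5), 1.0) < 0


# ---------------------------------------------------------------------------
# clearance / ingestion against the constant-clearance forward model
# ---------------------------------------------------------------------------

def _frost_model_oracle(f_star, k, mu, n0, c0, t=1.0, dt=0.001):
    """Fine-step simulation of the classic grazing model itself:
    prey grow at k and are removed at per-capita clearance f_star by
    exponentially growing grazers.  Tracks consumption for the true
    time-averaged ingestion per grazer per day."""
    steps = round(t / dt)
    n, c = n0, c0
    consumed = 0.0
    int_n = 0.0
    for _ in range(steps):
        removal = f_star * n * c * dt
        consumed += removal
        int_n += n * dt
        c = c + k * c * dt - removal
        n = n * math.exp(mu * dt)
    return n, c, consumed / int_n


def test_clearance_ingestion_recovers_constant_clearance():
    # moderate daily rates, where the estimator's piecewise-exponential
    # assumptions hold; the covariance of prey and grazer trajectories
    # grows quadratically with the rates
    f_star, k, mu = 1e-3, 0.3, 0.25
    n0, c0 = 20.0, 3e4
    n1, c1, i_true = _frost_model_oracle(f_star, k, mu, n0, c0)
    iv = Interval("c", 0.0, 1.0, N0=n0, N1=n1, C0=c0, C1=c1, k_control=k)
    res = clearance_ingestion(iv)
    assert res.F == pytest.approx(f_star, rel=0.01)
    assert res.I == pytest.approx(i_true, rel=0.01)
    assert not res.flags


def test_zero_grazing_gives_zero_clearance():
    iv = Interval("c", 0.0, 1.0, N0=20.0, N1=20.0,
                  C0=1e4, C1=1e4 * math.exp(0.5), k_control=0.5)
    res = clearance_ingestion(iv)
    assert res.g == pytest.approx(0.0, abs=1e-12)
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.I == pytest.approx(0.0, abs=1e-12)


def test_depleted_prey_substitutes_detection_limit():
    iv = Interval("c", 0.0, 1.0, N0=20.0, N1=25.0, C0=5e3, C1=0.0, k_control=0.3)
    res = clearance_ingestion(iv, GrazingConfig(detection_limit=0.5))
    assert "depleted_prey" in res.flags
    assert res.g == pytest.approx(0.3 - math.log(0.5 / 5e3), rel=1e-9)


def test_negative_grazing_policies():
    iv = Interval("c", 0.0, 1.0, N0=20.0, N1=20.0,
                  C0=1e4, C1=1e4 * math.exp(0.8), k_control=0.5)
    flagged = clearance_ingestion(iv, GrazingConfig(negative_grazing_policy="flag_zero"))
    assert "negative_grazing" in flagged.flags
    assert flagged.I == 0.0 and flagged.F == 0.0
    assert flagged.g == pytest.approx(-0.3, rel=1e-9)  # raw g retained
    kept = clearance_ingestion(iv, GrazingConfig(negative_grazing_policy="keep_negative"))
    assert kept.I < 0 and "negative_grazing" in kept.flags


def test_missing_control_skips_ingestion():
    iv = Interval("c", 0.0, 1.0, N0=20.0, N1=25.0, C0=1e4, C1=8e3, k_control=None)
    res = clearance_ingestion(iv)
    assert res.mu_y is not None
    assert res.I is None and "missing_control" in res.flags


# ---------------------------------------------------------------------------
# interval construction
# ---------------------------------------------------------------------------

def _count(cid, day, species, density, phase="none"):
    return CountObservation(cid, "T", day, species, density, phase=phase)


def test_acclimation_five_days_gives_four_intervals():
    counts = []
    for d in range(5):
        for sp, dens in (("ciliate", 15.0), ("prey", 4e4)):
            if d > 0:
                counts.append(_count("c1", float(d), sp, dens * 1.5, "pre_dilution"))
            if d < 4:
                counts.append(_count("c1", float(d), sp, dens, "post_dilution"))
    ivs = build_intervals(counts)
    assert len(ivs) == 4
    assert [(iv.t0, iv.t1) for iv in ivs] == [(0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0)]
    # post-dilution density starts each window
    assert all(iv.N0 == 15.0 and iv.N1 == 22.5 for iv in ivs)


def test_starvation_sampling_days_pair_consecutively():
    counts = []
    for d in (2.0, 5.0, 7.0, 9.0):
        counts.append(_count("c1", d, "ciliate", 200.0 * math.exp(-0.3 * d)))
        counts.append(_count("c1", d, "prey", 10.0))
    ivs = build_intervals(counts)
    assert [(iv.t0, iv.t1) for iv in ivs] == [(2.0, 5.0), (5.0, 7.0), (7.0, 9.0)]


def test_unlabelled_counts_default_to_consecutive_days():
    counts = [_count("c1", float(d), "ciliate", 100.0 + d) for d in range(3)]
    ivs = build_intervals(counts)
    assert [(iv.t0, iv.t1) for iv in ivs] == [(0.0, 1.0), (1.0, 2.0)]
    assert all(iv.k_control is None for iv in ivs)


def test_control_matching_per_interval():
    counts = [_count("c1", 0.0, "ciliate", 15.0), _count("c1", 1.0, "ciliate", 20.0),
              _count("c1", 0.0, "prey", 1e4), _count("c1", 1.0, "prey", 8e3)]
    controls = [_count("ctrl", 0.0, "prey", 1e4, "post_dilution"),
                _count("ctrl", 1.0, "prey", 1e4 * math.exp(0.4), "pre_dilution")]
    (iv,) = build_intervals(counts, controls)
    assert iv.k_control == pytest.approx(0.4, rel=1e-9)


# ---------------------------------------------------------------------------
# counting-noise robustness
# ---------------------------------------------------------------------------

def test_growth_rate_median_error_under_poisson_counting():
    """At the protocol's 200-individual counting effort, the growth-rate
    estimate over a 2-day window keeps its median relative error below 5%."""
    rng = np.random.default_rng(42)
    mu, t, volume = 0.7, 2.0, 2.0
    n0_true = 200.0 / volume          # expected tally 200 at the start
    n1_true = n0_true * math.exp(mu * t)
    errs = []
    for _ in range(1000):
        c0 = rng.poisson(n0_true * volume) / volume
        c1 = rng.poisson(n1_true * volume) / volume
        est = growth_rate(c0, c1, t)
        if est is not None:
            errs.append(abs(est - mu) / mu)
    assert np.median(errs) < 0.05
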