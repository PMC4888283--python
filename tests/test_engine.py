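"""Life-table engine: schedules, the seven endpoints, and their identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lifetab import (
    CohortSchedule,
    IndividualRecord,
    birth_rate,
    build_schedule,
    cohort_generation_time,
    death_rate,
    demographic_parameters,
    doubling_time,
    finite_rate,
    intrinsic_rate,
    net_reproductive_rate,
)
from conftest import random_schedule


# ---------------------------------------------------------------- oracles

def loop_r0(s):
    total = 0.0
    for x in range(1, s.horizon_day + 1):
        total += s.lx[x - 1] * s.mx[x - 1]
    return total


def loop_tc(s):
    num = den = 0.0
    for x in range(1, s.horizon_day + 1):
        num += x * s.lx[x - 1] * s.mx[x - 1]
        den += s.lx[x - 1] * s.mx[x - 1]
    return num / den


def loop_b(s, r):
    total = 0.0
    for x in range(1, s.horizon_day + 1):
        l_next = s.lx[x] if x < s.horizon_day else 0.0
        big_l = (s.lx[x - 1] + l_next) / 2.0
        total += math.exp(-r * (x + 1)) * big_l
    return 1.0 / total


def lotka_sum(s, r):
    return sum(
        math.exp(-r * x) * s.lx[x - 1] * s.mx[x - 1]
        for x in range(1, s.horizon_day + 1)
    )


def bisect_lotka(s, lo=-2.0, hi=5.0, iters=80):
    """Independent interval-bisection root of the renewal equation."""
    while lotka_sum(s, lo) < 1.0:
        lo -= hi - lo
    while lotka_sum(s, hi) > 1.0:
        hi += hi - lo
    for _ in range(iters):
        mid = (lo + hi) / 2.0
        if lotka_sum(s, mid) > 1.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------- build_schedule

class TestBuildSchedule:
    def test_death_counts_alive_through_death_day(self):
        # deaths on days 3 and 5: the day-3 death is alive through day 3
        recs = [
            IndividualRecord(1, 1, last_day=3),
            IndividualRecord(1, 2, last_day=5),
        ]
        s = build_schedule(recs, horizon_day=5)
        assert s.lx.tolist() == [1.0, 1.0, 1.0, 0.5, 0.5]

    def test_fecundity_is_per_survivor(self):
        recs = [IndividualRecord(1, 1, last_day=7, offspring={7: 4})]
        s = build_schedule(recs, horizon_day=7)
        assert s.mx[6] == 4.0
        assert net_reproductive_rate(s) == 4.0

    def test_horizon_beyond_max_lifespan_is_idempotent(self):
        recs = [
            IndividualRecord(1, 1, last_day=4, offspring={3: 2}),
            IndividualRecord(1, 2, last_day=6, offspring={5: 1}),
        ]
        a = build_schedule(recs, horizon_day=6)
        b = build_schedule(recs, horizon_day=20)
        assert np.array_equal(a.lx, b.lx[:6]) and np.array_equal(a.mx, b.mx[:6])
        assert np.all(b.lx[6:] == 0.0) and np.all(b.mx[6:] == 0.0)
        pa = demographic_parameters(a)
        pb = demographic_parameters(b)
        assert pa.R0 == pb.R0 and pa.r == pb.r

    def test_offspring_beyond_horizon_dropped(self):
        recs = [IndividualRecord(1, 1, last_day=10, offspring={3: 2, 9: 5})]
        s = build_schedule(recs, horizon_day=7)
        assert net_reproductive_rate(s) == 2.0

    def test_empty_replicate_rejected(self):
        with pytest.raises(ValueError):
            build_schedule([], horizon_day=5)


# ---------------------------------------------------------------- sum oracles

@pytest.mark.parametrize("seed", range(10))
def test_r0_tc_b_match_loop_oracles(seed):
    rng = np.random.default_rng(seed)
    s = random_schedule(rng)
    assert net_reproductive_rate(s) == pytest.approx(loop_r0(s), abs=1e-12)
    if loop_r0(s) > 0:
        assert cohort_generation_time(s) == pytest.approx(loop_tc(s), abs=1e-10)
    for r in (-0.1, 0.0, 0.3):
        assert birth_rate(s, r) == pytest.approx(loop_b(s, r), rel=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_lotka_root_matches_bisection_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    s = random_schedule(rng)
    r = intrinsic_rate(s, method="lotka")
    assert abs(lotka_sum(s, r) - 1.0) < 1e-10
    assert r == pytest.approx(bisect_lotka(s), abs=1e-9)


# ---------------------------------------------------------------- closed forms

def single_age_schedule(age: int, mass: float, horizon: int = 12) -> CohortSchedule:
    lx = np.ones(horizon)
    mx = np.zeros(horizon)
    mx[age - 1] = mass
    return CohortSchedule(lx=lx, mx=mx, n_founders=1)


def test_approximate_and_lotka_coincide_for_single_age_reproduction():
    # with all reproduction at age a, both estimators give ln(R0)/a exactly
    for age, mass in [(7, 14.07), (4, 2.5), (10, 100.0)]:
        s = single_age_schedule(age, mass)
        closed = math.log(mass) / age
        assert intrinsic_rate(s, "approximate") == pytest.approx(closed, rel=1e-14)
        assert intrinsic_rate(s, "lotka") == pytest.approx(closed, rel=1e-9)
        assert cohort_generation_time(s) == pytest.approx(age, rel=1e-14)


def test_first_week_single_clutch_pattern():
    # one clutch of 14.07 at day 7 with full survival: the classical
    # first-week column (R0 14.07, T 7.00, r 0.378)
    s = single_age_schedule(7, 14.07)
    p = demographic_parameters(s, method="approximate")
    assert p.R0 == pytest.approx(14.07)
    assert p.T == pytest.approx(7.00)
    assert p.r == pytest.approx(0.378, abs=5e-4)


def test_symmetric_mass_generation_time():
    lx = np.ones(8)
    mx = np.zeros(8)
    mx[3] = mx[7] = 2.0  # equal l*m mass at days 4 and 8
    s = CohortSchedule(lx=lx, mx=mx, n_founders=1)
    assert cohort_generation_time(s) == pytest.approx(6.0)


def test_single_age_class_birth_rate():
    s = CohortSchedule(lx=np.array([1.0]), mx=np.array([2.0]), n_founders=1)
    assert birth_rate(s, 0.0) == pytest.approx(2.0)  # L1 = 1/2, b = 1/(1/2)


@pytest.mark.parametrize(
    "r, lam", [(0.227, 1.255), (0.202, 1.224), (0.0, 1.0)]
)
def test_finite_rate(r, lam):
    assert finite_rate(r) == pytest.approx(lam, abs=5e-4)


@pytest.mark.parametrize(
    "r, dt", [(0.227, 3.05), (math.log(2), 1.0), (0.402, 1.72)]
)
def test_doubling_time(r, dt):
    assert doubling_time(r) == pytest.approx(dt, abs=5e-3)


def test_doubling_time_degenerate_r():
    assert doubling_time(0.0) == math.inf
    assert doubling_time(-0.1) == pytest.approx(math.log(2) / 0.1)
    assert math.isnan(doubling_time(math.nan))


@pytest.mark.parametrize(
    "b, r, d", [(0.184, 0.202, -0.018), (0.204, 0.227, -0.023), (0.2, 0.2, 0.0)]
)
def test_death_rate(b, r, d):
    assert death_rate(b, r) == pytest.approx(d, abs=1e-12)


# ---------------------------------------------------------------- degenerate

def test_no_reproduction_flags_everything_undefined():
    s = CohortSchedule(lx=np.ones(5), mx=np.zeros(5), n_founders=3)
    p = demographic_parameters(s)
    assert p.R0 == 0.0
    for name in ("r", "lambda", "T", "DT", "b", "d"):
        assert not p.defined(name)


def test_declining_population_flag():
    s = single_age_schedule(5, 0.5)  # R0 < 1
    p = demographic_parameters(s)
    assert p.declining and p.r < 0
    assert p.DT == pytest.approx(math.log(2) / abs(p.r))


# ---------------------------------------------------------------- identities

@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), method=st.sampled_from(["approximate", "lotka"]))
def test_identity_suite(seed, method):
    """lambda = e^r, DT r = ln 2, T r = ln R0, b - d = r, to 1e-12."""
    rng = np.random.default_rng(seed)
    s = random_schedule(rng)
    p = demographic_parameters(s, method=method)
    if p.R0 <= 1.0:
        return
    assert p.lam == pytest.approx(math.exp(p.r), abs=1e-12)
    assert p.DT * p.r == pytest.approx(math.log(2.0), abs=1e-12)
    assert p.T * p.r == pytest.approx(math.log(p.R0), abs=1e-12)
    assert p.b - p.d == pytest.approx(p.r, abs=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_lotka_r_never_decreases_with_horizon(seed):
    """Adding non-negative l*m mass cannot lower the Euler-Lotka root."""
    rng = np.random.default_rng(seed)
    s = random_schedule(rng)
    horizons = [h for h in range(2, s.horizon_day + 1)]
    last = -math.inf
    for h in horizons:
        t = s.truncated(h)
        if net_reproductive_rate(t) <= 0:
            continue
        r = intrinsic_rate(t, method="lotka")
        assert r >= last - 1e-9
        last = r


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_r0_nondecreasing_in_horizon(seed):
    rng = np.random.default_rng(seed)
    s = random_schedule(rng)
    r0s = [net_reproductive_rate(s.truncated(h)) for h in range(1, s.horizon_day + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(r0s, r0s[1:]))


def test_schedule_validation():
    with pytest.raises(ValueError):
        CohortSchedule(lx=np.array([0.5, 0.8]), mx=np.zeros(2), n_founders=1)
    with pytest.raises(ValueError):
        CohortSchedule(lx=np.array([1.0, 0.0]), mx=np.array([0.0, 1.0]), n_founders=1)
    with pytest.raises(ValueError):
        intrinsic_rate(single_age_schedule(5, 2.0), method="nope")
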