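import math

import numpy as np
import pytest

from lifetab import CohortSchedule, IndividualRecord, make_cohort


def random_schedule(rng: np.random.Generator, max_days: int = 30) -> CohortSchedule:
    """Random valid schedule: non-increasing l_x, non-negative m_x."""
    n_days = int(rng.integers(3, max_days + 1))
    drops = rng.uniform(0.0, 0.15, size=n_days)
    lx = np.clip(1.0 - np.cumsum(drops), 0.0, 1.0)
    mx = rng.uniform(0.0, 8.0, size=n_days) * (rng.random(n_days) < 0.6)
    mx[lx == 0.0] = 0.0
    if not np.any(lx * mx > 0):  # force some reproductive mass
        mx[0] = 1.0
    return CohortSchedule(lx=lx, mx=mx, n_founders=10)


@pytest.fixture
def rng():
    return np.random.default_rng(20160525)


@pytest.fixture
def two_rep_cohort():
    """Tiny hand-built cohort: 2 replicates x 2 individuals, 10-day span."""
    records = [
        IndividualRecord(1, 1, last_day=8, censored=False, offspring={6: 5, 7: 3}),
        IndividualRecord(1, 2, last_day=10, censored=True, offspring={6: 4, 9: 6}),
        IndividualRecord(2, 1, last_day=5, censored=False, offspring={4: 2}),
        IndividualRecord(2, 2, last_day=10, censored=True, offspring={6: 7, 9: 1}),
    ]
    return make_cohort("toy", records)


def assert_params_equal(a, b):
    for name in ("R0", "r", "lambda", "T", "DT", "b", "d"):
        va, vb = a.value(name), b.value(name)
        assert (math.isnan(va) and math.isnan(vb)) or va == vb, name
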