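"""Age-schedule construction and demographic parameter estimation.

From a replicate's individual records this module builds the classical
cohort schedule — survivorship ``l_x`` (fraction of founders alive on day x)
and age-specific fecundity ``m_x`` (offspring per surviving female on day x)
— and derives seven demographic endpoints:

======  =============================================================
R0      net reproductive rate, sum l_x m_x (offspring / female / generation)
T       mean generation time (days)
r       intrinsic rate of increase (per day)
lambda  finite rate of increase, e^r (per day)
DT      doubling time, ln(2)/r (days)
b       intrinsic birth rate in the stable age distribution (per day)
d       intrinsic death rate, b - r (per day)
======  =============================================================

Two estimators of r are offered.  The *approximate* estimator uses the
cohort generation time, r = ln(R0)/T_c with T_c = sum(x l_x m_x)/sum(l_x m_x);
it is the default because the weekly tables this pipeline emulates are
internally consistent with it (and unlike the exact root it can decrease as
later reproduction is added, which those tables show).  The *lotka*
estimator solves the discrete Euler-Lotka renewal equation
``sum_x exp(-r x) l_x m_x = 1`` exactly by bracketed root finding.

Undefined quantities (e.g. every rate when R0 = 0) are reported as NaN and
flagged through :meth:`DemographicParameters.defined`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

from .cohort import IndividualRecord

__all__ = [
    "CohortSchedule",
    "DemographicParameters",
    "build_schedule",
    "net_reproductive_rate",
    "cohort_generation_time",
    "intrinsic_rate",
    "finite_rate",
    "doubling_time",
    "birth_rate",
    "death_rate",
    "demographic_parameters",
]

PARAMETER_NAMES = ("R0", "b", "d", "T", "DT", "r", "lambda")

#: absolute tolerance on the Euler-Lotka residual |sum - 1|
LOTKA_TOL = 1e-10


@dataclass(frozen=True)
class CohortSchedule:
    """Survivorship and fecundity by age for one replicate.

    ``lx[i]`` and ``mx[i]`` refer to day ``i + 1``; ``l`` at age 0 is 1 by
    convention (all founders alive at introduction) and is not stored.
    """

    lx: np.ndarray
    mx: np.ndarray
    n_founders: int

    def __post_init__(self) -> None:
        lx = np.asarray(self.lx, dtype=float)
        mx = np.asarray(self.mx, dtype=float)
        object.__setattr__(self, "lx", lx)
        object.__setattr__(self, "mx", mx)
        if lx.shape != mx.shape or lx.ndim != 1 or lx.size < 1:
            raise ValueError("lx and mx must be 1-D arrays of equal length >= 1")
        if np.any(lx < 0) or np.any(lx > 1):
            raise ValueError("survivorship l_x must lie in [0, 1]")
        if np.any(np.diff(lx) > 1e-12):
            raise ValueError("survivorship l_x must be non-increasing")
        if np.any(mx < 0):
            raise ValueError("fecundity m_x must be non-negative")
        if np.any((lx == 0) & (mx > 0)):
            raise ValueError("m_x must be 0 where no survivor exists")

    @property
    def horizon_day(self) -> int:
        return int(self.lx.size)

    @property
    def ages(self) -> np.ndarray:
        """Ages in days, 1..horizon_day."""
        return np.arange(1, self.horizon_day + 1, dtype=float)

    def truncated(self, horizon_day: int) -> "CohortSchedule":
        """Schedule restricted to ages <= horizon_day (padding with zeros
        beyond the stored horizon)."""
        if horizon_day < 1:
            raise ValueError("horizon_day must be >= 1")
        h = min(horizon_day, self.horizon_day)
        lx = np.zeros(horizon_day)
        mx = np.zeros(horizon_day)
        lx[:h] = self.lx[:h]
        mx[:h] = self.mx[:h]
        return CohortSchedule(lx=lx, mx=mx, n_founders=self.n_founders)


def build_schedule(
    records: Iterable[IndividualRecord], horizon_day: int
) -> CohortSchedule:
    """Build the ``(l_x, m_x)`` schedule of one replicate up to a horizon.

    Only observations on days <= ``horizon_day`` are used: survival beyond
    the horizon is censored and offspring beyond it are dropped, so a
    schedule truncated at day 7w is exactly the week-w partial life table.

    ``l_x`` counts an animal that dies on day x as alive on day x (a brood
    released on the death day is attributable); ``m_x`` is total offspring
    on day x divided by the number alive, and 0 when none are alive.
    """
    recs = list(records)
    if not recs:
        raise ValueError("cannot build a schedule from an empty replicate")
    if horizon_day < 1:
        raise ValueError("horizon_day must be >= 1")
    n = len(recs)
    days = np.arange(1, horizon_day + 1)
    alive = np.zeros(horizon_day, dtype=float)
    births = np.zeros(horizon_day, dtype=float)
    for rec in recs:
        last = min(rec.last_day, horizon_day)
        alive[:last] += 1.0
        for day, count in rec.offspring.items():
            if day <= horizon_day:
                births[day - 1] += count
    lx = alive / n
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(alive > 0, births / np.maximum(alive, 1.0), 0.0)
    return CohortSchedule(lx=lx, mx=mx, n_founders=n)


def net_reproductive_rate(s: CohortSchedule) -> float:
    """R0 = sum_x l_x m_x."""
    return float(np.sum(s.lx * s.mx))


def cohort_generation_time(s: CohortSchedule) -> float:
    """T_c = sum_x x l_x m_x / sum_x l_x m_x; NaN when R0 = 0."""
    r0 = net_reproductive_rate(s)
    if r0 <= 0.0:
        return math.nan
    return float(np.sum(s.ages * s.lx * s.mx) / r0)


def _lotka_residual(r: float, s: CohortSchedule) -> float:
    return float(np.sum(np.exp(-r * s.ages) * s.lx * s.mx)) - 1.0


def _solve_lotka(s: CohortSchedule) -> float:
    """Root of sum exp(-r x) l_x m_x = 1, by bracketed Brent iteration.

    The left side is strictly decreasing in r whenever any l_x m_x > 0, so
    the root is unique.  The initial bracket [-2, 5] per day is expanded
    geometrically if needed.
    """
    lo, hi = -2.0, 5.0
    for _ in range(60):
        if _lotka_residual(lo, s) > 0.0:
            break
        lo -= hi - lo
    else:
        raise ArithmeticError("Euler-Lotka bracket expansion failed (low end)")
    for _ in range(60):
        if _lotka_residual(hi, s) < 0.0:
            break
        hi += hi - lo
    else:
        raise ArithmeticError("Euler-Lotka bracket expansion failed (high end)")
    root = brentq(_lotka_residual, lo, hi, args=(s,), xtol=1e-14, rtol=8.9e-16)
    resid = _lotka_residual(root, s)
    if abs(resid) > LOTKA_TOL:
        raise ArithmeticError(
            f"Euler-Lotka solver did not converge: r={root!r}, "
            f"|residual|={abs(resid):.3e} > {LOTKA_TOL:g}"
        )
    return float(root)


def intrinsic_rate(s: CohortSchedule, method: str = "approximate") -> float:
    """Intrinsic rate of increase r (per day).

    ``approximate``: r = ln(R0)/T_c.  ``lotka``: exact Euler-Lotka root.
    NaN when R0 = 0 (no reproduction before the horizon).
    """
    r0 = net_reproductive_rate(s)
    if r0 <= 0.0:
        return math.nan
    if method == "approximate":
        return float(math.log(r0) / cohort_generation_time(s))
    if method == "lotka":
        return _solve_lotka(s)
    raise ValueError(f"unknown method {method!r}; use 'approximate' or 'lotka'")


def finite_rate(r: float) -> float:
    """lambda = e^r, the daily multiplicative growth factor."""
    return float(np.exp(r))


def doubling_time(r: float) -> float:
    """DT = ln(2)/r days for r > 0; +inf at r = 0.

    For r < 0 the returned magnitude ln(2)/|r| is the population halving
    time; callers should carry a declining-population flag (see
    :func:`demographic_parameters`).
    """
    if math.isnan(r):
        return math.nan
    if r == 0.0:
        return math.inf
    return float(math.log(2.0) / abs(r))


def birth_rate(s: CohortSchedule, r: float) -> float:
    """Intrinsic birth rate b of the stable age distribution.

    b = 1 / sum_x exp(-r (x+1)) L_x with L_x = (l_x + l_{x+1})/2 the
    mid-interval person-days lived (l beyond the horizon taken as 0) — the
    stable-age formulation of classical cohort life-table practice.
    """
    if math.isnan(r):
        return math.nan
    l_next = np.append(s.lx[1:], 0.0)
    big_l = (s.lx + l_next) / 2.0
    terms = np.exp(-r * (s.ages + 1.0)) * big_l
    total = float(np.sum(terms))
    if not math.isfinite(total) or total <= 0.0:
        raise ArithmeticError(
            f"birth-rate sum diverged or vanished (r={r!r}, sum={total!r})"
        )
    return 1.0 / total


def death_rate(b: float, r: float) -> float:
    """d = b - r (negative in a growing stable population whenever b < r)."""
    return b - r


@dataclass(frozen=True)
class DemographicParameters:
    """The seven demographic endpoints of one schedule.

    Undefined entries are NaN; ``defined(name)`` reports availability.
    ``declining`` marks r < 0, in which case ``DT`` holds the halving time
    magnitude rather than a doubling time.
    """

    R0: float
    r: float
    lam: float
    T: float
    DT: float
    b: float
    d: float
    method: str
    declining: bool = False

    def defined(self, name: str) -> bool:
        return not math.isnan(self.value(name))

    def value(self, name: str) -> float:
        key = {"lambda": "lam"}.get(name, name)
        return float(getattr(self, key))

    def as_dict(self) -> dict[str, float]:
        return {name: self.value(name) for name in PARAMETER_NAMES}


def demographic_parameters(
    s: CohortSchedule, method: str = "approximate"
) -> DemographicParameters:
    """Compute all seven endpoints from a schedule.

    Under ``approximate`` the generation time is the cohort generation time
    T_c (and T = ln(R0)/r holds by construction); under ``lotka`` T is
    reported as ln(R0)/r with the exact root.  When R0 = 0 every rate is
    NaN-flagged.
    """
    r0 = net_reproductive_rate(s)
    if r0 <= 0.0:
        nan = math.nan
        return DemographicParameters(
            R0=r0, r=nan, lam=nan, T=nan, DT=nan, b=nan, d=nan, method=method
        )
    r = intrinsic_rate(s, method=method)
    lam = finite_rate(r)
    if method == "approximate":
        t = cohort_generation_time(s)
    else:
        t = math.log(r0) / r if r != 0.0 else math.nan
    dt = doubling_time(r)
    b = birth_rate(s, r)
    d = death_rate(b, r)
    return DemographicParameters(
        R0=r0, r=r, lam=lam, T=t, DT=dt, b=b, d=d,
        method=method, declining=bool(r < 0.0),
    )
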