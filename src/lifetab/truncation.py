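"""Cumulative weekly truncation of a cohort and cross-replicate summaries.

A week-w partial life table uses every observation up to day 7w: survival is
censored at the horizon and offspring beyond it are dropped.  The last week
W = ceil(max observed day / 7) uses all data and *is* the full life table,
so the week-W column of any summary coincides exactly with a standalone
full-life-cycle analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort
from .engine import (
    PARAMETER_NAMES,
    DemographicParameters,
    build_schedule,
    demographic_parameters,
)

__all__ = [
    "TruncationSeries",
    "weekly_truncations",
    "summarize",
    "full_life_table",
    "truncate_cohort",
]


def truncate_cohort(cohort: Cohort, week: int) -> Cohort:
    """Cohort as it would have been observed for only ``week`` weeks.

    Survival is censored at day 7·week and offspring beyond it dropped.
    Truncating at week w and then at v < w equals truncating at v directly.
    """
    from .cohort import IndividualRecord, make_cohort

    horizon = 7 * week
    records = []
    for rec in cohort.records:
        if rec.last_day <= horizon:
            records.append(rec)
        else:
            records.append(
                IndividualRecord(
                    replicate_id=rec.replicate_id,
                    individual_id=rec.individual_id,
                    last_day=horizon,
                    censored=True,
                    offspring={d: c for d, c in rec.offspring.items() if d <= horizon},
                )
            )
    return make_cohort(cohort.species_label, records)


@dataclass(frozen=True)
class TruncationSeries:
    """Per-replicate demographic parameters at every weekly horizon.

    ``table`` is long-format with columns
    ``week, replicate, parameter, value`` (value NaN when undefined);
    ``parameters`` maps ``(week, replicate_id)`` to the full
    :class:`DemographicParameters` object.
    """

    species_label: str
    method: str
    n_weeks: int
    table: pd.DataFrame
    parameters: Dict[Tuple[int, int], DemographicParameters]

    @property
    def replicate_ids(self) -> list[int]:
        return sorted(self.table["replicate"].unique())

    def values(self, parameter: str, week: int) -> np.ndarray:
        """Replicate values of one parameter at one week, replicate-ordered."""
        sub = self.table[
            (self.table["week"] == week) & (self.table["parameter"] == parameter)
        ].sort_values("replicate")
        return sub["value"].to_numpy(dtype=float)


def weekly_truncations(cohort: Cohort, method: str = "approximate") -> TruncationSeries:
    """Build partial life tables at horizons 7, 14, ..., 7W days.

    Each replicate is truncated and analysed independently; week W equals
    the untruncated analysis.  Weeks where a replicate has no reproduction
    yet (R0 = 0) carry NaN rates and a warning.
    """
    n_weeks = math.ceil(cohort.max_observed_day / 7)
    rows = []
    params: Dict[Tuple[int, int], DemographicParameters] = {}
    undefined_weeks = set()
    for week in range(1, n_weeks + 1):
        horizon = 7 * week
        for rid, recs in cohort.replicates().items():
            schedule = build_schedule(recs, horizon_day=horizon)
            pars = demographic_parameters(schedule, method=method)
            params[(week, rid)] = pars
            if not pars.defined("r"):
                undefined_weeks.add(week)
            for name, value in pars.as_dict().items():
                rows.append(
                    {"week": week, "replicate": rid, "parameter": name, "value": value}
                )
    if undefined_weeks:
        warnings.warn(
            f"rate parameters undefined (no reproduction yet) at week(s) "
            f"{sorted(undefined_weeks)}; these cells are NaN and excluded "
            "from downstream statistics",
            stacklevel=2,
        )
    table = pd.DataFrame(rows, columns=["week", "replicate", "parameter", "value"])
    return TruncationSeries(
        species_label=cohort.species_label,
        method=method,
        n_weeks=n_weeks,
        table=table,
        parameters=params,
    )


def full_life_table(cohort: Cohort, method: str = "approximate") -> Dict[int, DemographicParameters]:
    """Standalone full-life-cycle analysis, one result per replicate.

    Identical (bit-for-bit) to the week-W entries of
    :func:`weekly_truncations` — both analyse the horizon 7W days.
    """
    horizon = 7 * math.ceil(cohort.max_observed_day / 7)
    return {
        rid: demographic_parameters(
            build_schedule(recs, horizon_day=horizon), method=method
        )
        for rid, recs in cohort.replicates().items()
    }


def summarize(series: TruncationSeries, dispersion: str = "sem") -> pd.DataFrame:
    """Mean and dispersion of each parameter per week across replicates.

    Returns a tidy frame with columns ``parameter, week, mean, disp, n``.
    ``dispersion`` is ``"sem"`` (SD/sqrt(n)) or ``"sd"``; with a single
    replicate the dispersion is NaN-flagged.  NaN replicate values
    (undefined parameters) are excluded cell-wise.
    """
    if dispersion not in ("sem", "sd"):
        raise ValueError("dispersion must be 'sem' or 'sd'")
    rows = []
    for week in range(1, series.n_weeks + 1):
        for name in PARAMETER_NAMES:
            vals = series.values(name, week)
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            mean = float(np.mean(vals)) if n else math.nan
            if n >= 2:
                # an infinite cell (DT at r = 0) gives mean inf, dispersion NaN
                with np.errstate(invalid="ignore"):
                    sd = float(np.std(vals, ddof=1))
                disp = sd / math.sqrt(n) if dispersion == "sem" else sd
            else:
                disp = math.nan
            rows.append(
                {"parameter": name, "week": week, "mean": mean, "disp": disp, "n": n}
            )
    return pd.DataFrame(rows, columns=["parameter", "week", "mean", "disp", "n"])
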