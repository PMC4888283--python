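"""Reading and writing cohort records and weekly report tables.

Cohort file dialect
-------------------
Long-format CSV, one row per individual-day, columns
``species,replicate,individual,day,alive,offspring`` with ``alive`` in
{0, 1}.  Rows run from day 1 through the animal's last day.  A final row
with ``alive=0`` marks the day the animal was found dead (normally with
``offspring=0``; a brood found with the body is kept on that row so the
file round-trips).  An individual whose last row has ``alive=1`` is
censored on that day — no death is imputed.
"""

from __future__ import annotations

import math
from os import PathLike
from typing import Dict, Union

import pandas as pd

from .cohort import Cohort, IndividualRecord, make_cohort
from .engine import PARAMETER_NAMES

__all__ = ["read_cohort", "write_cohort", "write_weekly_report", "CohortFormatError"]

REQUIRED_COLUMNS = ("replicate", "individual", "day", "alive", "offspring")

PathType = Union[str, PathLike]


class CohortFormatError(ValueError):
    """The file does not conform to the cohort CSV dialect."""


def _require_int(series: pd.Series, column: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.isna().any():
        bad = series[numeric.isna()].iloc[0]
        raise CohortFormatError(f"column {column!r}: non-numeric value {bad!r}")
    if (numeric != numeric.round()).any():
        bad = numeric[numeric != numeric.round()].iloc[0]
        raise CohortFormatError(f"column {column!r}: non-integer value {bad!r}")
    return numeric.astype(int)


def read_cohort(path: PathType, format: str = "csv") -> Cohort:
    """Read a long-format daily-record CSV into a validated :class:`Cohort`.

    The death day of an individual is the day of its ``alive=0`` row when
    present; otherwise the individual is censored at its last recorded day.
    Offspring recorded after an individual's last day raise a validation
    error naming the individual.
    """
    if format != "csv":
        raise ValueError(f"unknown format {format!r}; only 'csv' is supported")
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {missing}")
    for col in ("replicate", "individual", "day", "alive", "offspring"):
        frame[col] = _require_int(frame[col], col)
    if not frame["alive"].isin((0, 1)).all():
        raise CohortFormatError("column 'alive' must contain only 0 or 1")
    if (frame["day"] < 1).any():
        raise CohortFormatError("column 'day' must contain integers >= 1")
    if (frame["offspring"] < 0).any():
        raise CohortFormatError("column 'offspring' must be non-negative")
    species = (
        str(frame["species"].iloc[0]) if "species" in frame.columns and len(frame)
        else "unknown"
    )
    records = []
    for (rep, ind), rows in frame.groupby(["replicate", "individual"], sort=True):
        rows = rows.sort_values("day")
        dead_rows = rows[rows["alive"] == 0]
        if len(dead_rows) > 1:
            raise CohortFormatError(
                f"individual {ind} in replicate {rep}: multiple death rows"
            )
        if len(dead_rows) == 1:
            death_day = int(dead_rows["day"].iloc[0])
            if death_day != int(rows["day"].max()):
                raise CohortFormatError(
                    f"individual {ind} in replicate {rep}: rows recorded after "
                    f"the death row (day {death_day})"
                )
            censored = False
            last_day = death_day
        else:
            censored = True
            last_day = int(rows["day"].max())
        offspring = {
            int(day): int(count)
            for day, count in zip(rows["day"], rows["offspring"])
            if count > 0
        }
        late = [d for d in offspring if d > last_day]
        if late:
            raise CohortFormatError(
                f"individual {ind} in replicate {rep}: offspring recorded on "
                f"day {min(late)} after its last day {last_day}"
            )
        records.append(
            IndividualRecord(
                replicate_id=int(rep),
                individual_id=int(ind),
                last_day=last_day,
                censored=censored,
                offspring=offspring,
            )
        )
    if not records:
        raise CohortFormatError("file contains no individual records")
    return make_cohort(species, records)


def write_cohort(cohort: Cohort, path: PathType) -> None:
    """Write a cohort to the long-format CSV dialect.

    One row per individual-day from day 1 through death/censoring, so the
    number of data rows equals the summed last days.  ``read_cohort``
    composed with ``write_cohort`` is the identity.
    """
    rows = []
    for rec in sorted(cohort.records, key=lambda r: (r.replicate_id, r.individual_id)):
        for day in range(1, rec.last_day + 1):
            alive = 1 if rec.censored or day < rec.last_day else 0
            rows.append(
                {
                    "species": cohort.species_label,
                    "replicate": rec.replicate_id,
                    "individual": rec.individual_id,
                    "day": day,
                    "alive": alive,
                    "offspring": rec.offspring_on(day),
                }
            )
    pd.DataFrame(
        rows,
        columns=["species", "replicate", "individual", "day", "alive", "offspring"],
    ).to_csv(path, index=False)


def write_weekly_report(
    summary: pd.DataFrame,
    path: PathType,
    dispersion: str = "sem",
    letters: Dict[str, Dict[int, str]] | None = None,
) -> None:
    """Write the weekly report table: parameters as rows, weeks as columns.

    ``summary`` is the tidy frame from :func:`lifetab.truncation.summarize`
    (columns ``parameter, week, mean, disp, n``).  Cells are formatted
    ``mean ± dispersion`` and each week gets a sidecar ``week_w_letter``
    column carrying the Dunnett significance letter ('a' throughout when no
    letters are supplied, i.e. nothing differs from the full table).
    """
    weeks = sorted(summary["week"].unique())
    if weeks != list(range(1, len(weeks) + 1)):
        raise ValueError(f"summary must cover weeks 1..W without gaps, got {weeks}")
    out_rows = []
    for name in PARAMETER_NAMES:
        sub = summary[summary["parameter"] == name].set_index("week")
        if len(sub) != len(weeks):
            raise ValueError(f"summary incomplete for parameter {name!r}")
        row: Dict[str, object] = {"parameter": name}
        for w in weeks:
            mean = sub.loc[w, "mean"]
            disp = sub.loc[w, "disp"]
            if math.isnan(mean):
                cell = "NA"
            elif math.isnan(disp):
                cell = f"{mean:.3f} ± NA"
            else:
                cell = f"{mean:.3f} ± {disp:.3f}"
            row[f"week_{w}"] = cell
            letter = "a"
            if letters and name in letters:
                letter = letters[name].get(w, "a")
            row[f"week_{w}_letter"] = letter
        out_rows.append(row)
    columns = ["parameter"]
    for w in weeks:
        columns += [f"week_{w}", f"week_{w}_letter"]
    pd.DataFrame(out_rows, columns=columns).to_csv(path, index=False)
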