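"""Individual-level cohort records for daily survival/fecundity studies.

A cohort is a set of founder females (grouped into replicates) introduced as
<24 h neonates and followed daily.  Day 1 is the first 24 h after
introduction.  Each individual carries the day it was last observed (its
death day, or the day it was censored at the observation horizon) and a
sparse map of day -> offspring count.

Conventions
-----------
* An animal whose record ends in a death is "alive on day x" for every
  x <= death_day: it may have released a brood on the day it died, so deaths
  take demographic effect the following day.
* An animal censored on day c contributes survival information through day c
  and nothing beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping


@dataclass(frozen=True)
class IndividualRecord:
    """One animal's fate within one replicate.

    Parameters
    ----------
    replicate_id : int
        Small integer label of the replicate (batch) the animal belongs to.
    individual_id : int
        Label unique within the replicate.
    last_day : int
        Death day, or censoring day when ``censored`` is True.  Positive.
    censored : bool
        True when the animal was still alive at its last observation.
    offspring : mapping day -> count
        Offspring released on each day (days with zero offspring omitted).
    """

    replicate_id: int
    individual_id: int
    last_day: int
    censored: bool = False
    offspring: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.last_day < 1:
            raise ValueError(
                f"individual {self.individual_id!r}: last_day must be >= 1, "
                f"got {self.last_day}"
            )
        for day, count in self.offspring.items():
            if not (isinstance(day, (int,)) and day >= 1):
                raise ValueError(
                    f"individual {self.individual_id!r}: offspring day {day!r} "
                    "is not a positive integer"
                )
            if not (isinstance(count, int) and count >= 0):
                raise ValueError(
                    f"individual {self.individual_id!r}: offspring count "
                    f"{count!r} on day {day} is not a non-negative integer"
                )
            if day > self.last_day:
                raise ValueError(
                    f"individual {self.individual_id!r}: offspring recorded on "
                    f"day {day} after its last observed day {self.last_day}"
                )

    @property
    def death_day(self) -> int | None:
        """Death day, or None when the record is censored."""
        return None if self.censored else self.last_day

    def alive_on(self, day: int) -> bool:
        """Whether the animal counts as alive on ``day`` (1-based)."""
        return day <= self.last_day

    def offspring_on(self, day: int) -> int:
        return int(self.offspring.get(day, 0))


@dataclass(frozen=True)
class Cohort:
    """All records of one species' cohort, grouped by replicate."""

    species_label: str
    records: tuple[IndividualRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("cohort has no individual records")
        seen: set[tuple[int, int]] = set()
        for rec in self.records:
            key = (rec.replicate_id, rec.individual_id)
            if key in seen:
                raise ValueError(
                    f"duplicate individual id {rec.individual_id} in "
                    f"replicate {rec.replicate_id}"
                )
            seen.add(key)

    @property
    def replicate_ids(self) -> List[int]:
        return sorted({rec.replicate_id for rec in self.records})

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def replicate(self, replicate_id: int) -> List[IndividualRecord]:
        recs = [r for r in self.records if r.replicate_id == replicate_id]
        if not recs:
            raise KeyError(f"no such replicate: {replicate_id}")
        return recs

    def replicates(self) -> Dict[int, List[IndividualRecord]]:
        return {rid: self.replicate(rid) for rid in self.replicate_ids}

    @property
    def max_observed_day(self) -> int:
        return max(rec.last_day for rec in self.records)


def make_cohort(species_label: str, records: Iterable[IndividualRecord]) -> Cohort:
    return Cohort(species_label=species_label, records=tuple(records))
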