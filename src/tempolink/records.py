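"""Domain record types for ED visits and admitted hospital episodes.

Both record types carry minute-resolution, timezone-naive wall-clock
timestamps assembled from separate date and time source columns.  An ED
visit spans arrival (A) to departure (D); an admitted episode spans
admission (H) to separation (S).  All linkage and chaining logic operates
on these four timestamps plus the disposition code strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Sequence


def truncate_to_minute(dt: datetime) -> datetime:
    """Drop seconds and microseconds; administrative timestamps are hh:mm."""
    return dt.replace(second=0, microsecond=0)


@dataclass(frozen=True)
class EDVisit:
    """One emergency-department presentation.

    ``arrival_dt`` / ``departure_dt`` are minute-resolution local times.
    ``departure_status`` is the coded disposition on leaving the ED (the
    variable audited against found links).  ``flags`` records cleaning
    actions applied to this record (e.g. imputed time, repaired date).
    """

    participant_id: str
    visit_id: str
    arrival_dt: datetime
    departure_dt: datetime
    departure_status: str
    campus: str = ""
    visit_type: str = ""
    referred_by: str = ""
    diagnosis_codes: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def with_flag(self, flag: str) -> "EDVisit":
        return replace(self, flags=self.flags + (flag,))


@dataclass(frozen=True)
class HospitalEpisode:
    """One admitted episode of care (one care-type at one campus).

    A patient transferred between care-types or campuses before final
    discharge generates several episode records for one total hospital
    stay; ``separation_mode`` is the code that signals whether the episode
    ended in a planned transfer of care.
    """

    participant_id: str
    episode_id: str
    admission_dt: datetime
    separation_dt: datetime
    admission_type: str
    separation_mode: str
    admission_source: str = ""
    campus: str = ""
    care_type: str = ""
    diagnosis_codes: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def with_flag(self, flag: str) -> "HospitalEpisode":
        return replace(self, flags=self.flags + (flag,))


def check_unique_ids(ids: Iterable[str], kind: str) -> None:
    """Raise ``ValueError`` naming the first duplicated identifier."""
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


def group_by_participant(records: Sequence) -> dict[str, list]:
    out: dict[str, list] = {}
    for r in records:
        out.setdefault(r.participant_id, []).append(r)
    return out
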