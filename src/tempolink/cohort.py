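"""First-stage deterministic cohort-to-dataset identifier matching.

Emulates the exact-match rule used by state linkage services: a cohort
record and a dataset record refer to the same person only when all four
of Medicare number, first three letters of the first name, date of birth
and sex agree exactly after normalisation (a 100% deterministic match).
Operates only on synthetic identifiers in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class IdentifierRecord:
    """The four identifying fields plus an opaque record id."""

    record_id: str
    medicare_number: str
    first_name: str
    date_of_birth: str  # ISO date string
    sex: str


def _key(rec: IdentifierRecord) -> tuple[str, str, str, str] | None:
    """Normalised 4-field match key, or None if any field is missing."""
    fields = (rec.medicare_number, rec.first_name, rec.date_of_birth, rec.sex)
    if any(not f or not str(f).strip() for f in fields):
        return None
    name = "".join(str(rec.first_name).split()).lower()[:3]
    return (
        str(rec.medicare_number).strip(),
        name,
        str(rec.date_of_birth).strip(),
        str(rec.sex).strip().lower(),
    )


def match_cohort_to_dataset(
    cohort: Sequence[IdentifierRecord],
    dataset: Sequence[IdentifierRecord],
) -> tuple[list[tuple[str, str]], list[str]]:
    """Return (matched id pairs, excluded record ids).

    A pair ``(cohort_id, dataset_id)`` is emitted iff all four normalised
    fields are exactly equal.  Records missing any field are excluded
    from matching and reported in the second return value.
    """
    excluded: list[str] = []
    index: dict[tuple, list[str]] = {}
    for rec in dataset:
        k = _key(rec)
        if k is None:
            excluded.append(rec.record_id)
            continue
        index.setdefault(k, []).append(rec.record_id)
    pairs: list[tuple[str, str]] = []
    for rec in cohort:
        k = _key(rec)
        if k is None:
            excluded.append(rec.record_id)
            continue
        for did in index.get(k, ()):
            pairs.append((rec.record_id, did))
    return pairs, excluded
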