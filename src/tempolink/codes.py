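"""Disposition-code groupings used by linkage auditing and chaining.

Administrative ED and admitted-episode datasets encode where a patient
went on leaving the ED (``departure status``), how an admission arose
(``admission type``) and how an episode ended (``separation mode``).
The groupings below drive two things:

* chaining -- an episode whose separation mode indicates a *planned*
  transfer of care may open a continuous episode of care;
* auditing -- departure-status and admission-type groups define which
  records are *expected* to have a link, cross-checked against the links
  actually found.

Code values drift across collection years, so the groups are data, not
constants: they can be loaded from / saved to a YAML mapping file.  The
defaults use readable snake-case tokens for the standard code meanings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

_GROUP_FIELDS = (
    "departure_status_admission_expected",
    "departure_status_no_admission",
    "admission_type_ed_expected",
    "admission_type_uncertain",
    "separation_mode_transfer",
    "separation_mode_other",
)


@dataclass(frozen=True)
class CodeMaps:
    """Named, pairwise-disjoint sets of disposition codes."""

    # ED departure statuses implying the patient was admitted
    departure_status_admission_expected: frozenset[str] = frozenset(
        {"ward_this_hospital", "procedure_room_this_campus", "transfer_other_campus"}
    )
    # ED departure statuses implying no admission occurred
    departure_status_no_admission: frozenset[str] = frozenset(
        {"usual_residence", "left_before_completion", "died_in_ed"}
    )
    # the only admission type explicitly naming a preceding ED visit
    admission_type_ed_expected: frozenset[str] = frozenset(
        {"emergency_this_hospital"}
    )
    # admission types that cannot confirm a prior ED visit
    admission_type_uncertain: frozenset[str] = frozenset(
        {
            "waiting_list",
            "other_admission",
            "maternity",
            "statistical_admission",
            "other_emergency",
        }
    )
    # separation modes indicating a planned transfer of care: a statistical
    # separation (care-type change within the hospital) or transfer to
    # another hospital.  These open continuous episodes of care.
    separation_mode_transfer: frozenset[str] = frozenset(
        {"statistical_separation", "transfer_other_hospital"}
    )
    # known separation modes that end a stay (anything unmapped is also
    # treated as non-transfer but reported)
    separation_mode_other: frozenset[str] = frozenset(
        {"home", "died_in_hospital", "left_own_risk"}
    )

    def __post_init__(self) -> None:
        pairs = [
            ("departure_status_admission_expected", "departure_status_no_admission"),
            ("admission_type_ed_expected", "admission_type_uncertain"),
            ("separation_mode_transfer", "separation_mode_other"),
        ]
        for a, b in pairs:
            overlap = getattr(self, a) & getattr(self, b)
            if overlap:
                raise ValueError(f"code groups {a} and {b} overlap: {sorted(overlap)}")

    # -- group lookups ---------------------------------------------------
    def departure_status_group(self, code: str) -> str:
        """'admission_expected' | 'no_admission' | 'unmapped'."""
        if code in self.departure_status_admission_expected:
            return "admission_expected"
        if code in self.departure_status_no_admission:
            return "no_admission"
        return "unmapped"

    def admission_type_group(self, code: str) -> str:
        """'ed_expected' | 'uncertain' | 'unmapped'."""
        if code in self.admission_type_ed_expected:
            return "ed_expected"
        if code in self.admission_type_uncertain:
            return "uncertain"
        return "unmapped"

    def is_transfer_separation(self, code: str) -> bool:
        return code in self.separation_mode_transfer

    def is_known_separation(self, code: str) -> bool:
        return (
            code in self.separation_mode_transfer or code in self.separation_mode_other
        )

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, list[str]]:
        return {f: sorted(getattr(self, f)) for f in _GROUP_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "CodeMaps":
        kwargs = {f: frozenset(d[f]) for f in _GROUP_FIELDS if f in d}
        unknown = set(d) - set(_GROUP_FIELDS)
        if unknown:
            raise ValueError(f"unknown code-map groups: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeMaps":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


DEFAULT_CODE_MAPS = CodeMaps()
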