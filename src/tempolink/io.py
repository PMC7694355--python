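"""CSV ingestion and output for the ED-visit and episode dialects.

Input files are RFC-4180 CSV, UTF-8, with a header row.  Dates and clock
times arrive in *separate* columns (as administrative extracts deliver
them) and are assembled into minute-resolution datetimes here.  Column
names are mapped through a :class:`Dialect`; two canonical dialects are
provided, ``vemd_like`` for ED visits and ``vaed_like`` for admitted
episodes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .cleaning import CleaningReport, Policy, validate_and_clean
from .records import EDVisit, HospitalEpisode, check_unique_ids, truncate_to_minute


class ConfigError(ValueError):
    """Configuration problem (missing column, ambiguous dialect)."""


class RecordParseError(ValueError):
    """Row-level parse failure; message names row and field."""


MissingTimePolicy = Literal["impute-midnight", "drop", "error"]


@dataclass(frozen=True)
class Dialect:
    """Column-name map from canonical field names to file column names."""

    columns: dict[str, str]
    date_format: str = "%Y-%m-%d"
    time_formats: tuple[str, ...] = ("%H:%M", "%H:%M:%S", "%H%M")
    diagnosis_sep: str = ";"

    def col(self, canonical: str) -> str:
        return self.columns[canonical]


VISIT_FIELDS = (
    "participant_id", "visit_id", "arrival_date", "arrival_time",
    "departure_date", "departure_time", "departure_status",
)
VISIT_OPTIONAL = ("campus", "visit_type", "referred_by", "diagnosis_codes")

EPISODE_FIELDS = (
    "participant_id", "episode_id", "admission_date", "admission_time",
    "separation_date", "separation_time", "admission_type", "separation_mode",
)
EPISODE_OPTIONAL = ("admission_source", "campus", "care_type", "diagnosis_codes")

#: canonical ED-visit dialect (identity column names)
VEMD_LIKE = Dialect(columns={c: c for c in VISIT_FIELDS + VISIT_OPTIONAL})
#: canonical admitted-episode dialect
VAED_LIKE = Dialect(columns={c: c for c in EPISODE_FIELDS + EPISODE_OPTIONAL})


def assemble_datetime(
    date_field: str,
    time_field: str,
    policy: MissingTimePolicy = "impute-midnight",
    dialect: Dialect = VEMD_LIKE,
) -> tuple[datetime | None, bool]:
    """Combine separate date and clock-time strings into one datetime.

    Returns ``(datetime, imputed)``.  An empty time field is handled per
    ``policy``: ``impute-midnight`` yields 00:00 with ``imputed=True``;
    ``drop`` returns ``(None, True)`` so the caller can discard the row;
    ``error`` raises.  Seconds, if present, are truncated to the minute.
    """
    date_field = date_field.strip()
    time_field = time_field.strip()
    try:
        d = datetime.strptime(date_field, dialect.date_format)
    except ValueError as exc:
        raise RecordParseError(f"unparseable date {date_field!r}: {exc}") from None
    if not time_field:
        if policy == "impute-midnight":
            return d, True
        if policy == "drop":
            return None, True
        raise RecordParseError("missing clock time")
    for fmt in dialect.time_formats:
        try:
            t = datetime.strptime(time_field, fmt)
            return truncate_to_minute(
                d.replace(hour=t.hour, minute=t.minute, second=t.second)
            ), False
        except ValueError:
            continue
    raise RecordParseError(f"unparseable time {time_field!r}")


def _read_rows(source: str | Path, dialect: Dialect, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [dialect.col(c) for c in required if c in dialect.columns
               and dialect.col(c) not in df.columns]
    unmapped = [c for c in required if c not in dialect.columns]
    if unmapped:
        raise ConfigError(f"dialect does not map required fields: {unmapped}")
    if missing:
        raise ConfigError(f"{source}: missing mapped columns: {missing}")
    return df

def _opt(row, dialect: Dialect, canonical: str) -> str:
    name = dialect.columns.get(canonical)
    if name and name in row:
        return str(row[name]).strip()
    return ""


def _diag(row, dialect: Dialect) -> tuple[str, ...]:
    raw = _opt(row, dialect, "diagnosis_codes")
    return tuple(c for c in (s.strip() for s in raw.split(dialect.diagnosis_sep)) if c)


def read_visits(
    source: str | Path,
    dialect: Dialect = VEMD_LIKE,
    missing_time_policy: MissingTimePolicy = "impute-midnight",
    cleaning_policy: Policy = "strict",
) -> tuple[list[EDVisit], CleaningReport]:
    """Read an ED-visit CSV; assemble datetimes; validate and clean."""
    df = _read_rows(source, dialect, VISIT_FIELDS)
    report = CleaningReport(n_input=len(df))
    visits: list[EDVisit] = []
    for idx, row in df.iterrows():
        vid = str(row[dialect.col("visit_id")]).strip()
        try:
            arrival, a_imp = assemble_datetime(
                row[dialect.col("arrival_date")], row[dialect.col("arrival_time")],
                missing_time_policy, dialect)
            departure, d_imp = assemble_datetime(
                row[dialect.col("departure_date")], row[dialect.col("departure_time")],
                missing_time_policy, dialect)
        except RecordParseError as exc:
            raise RecordParseError(f"{source} row {idx} visit {vid!r}: {exc}") from None
        if arrival is None or departure is None:
            report.add(vid, "missing-clock-time", "dropped")
            continue
        flags: tuple[str, ...] = ()
        if a_imp or d_imp:
            flags = ("imputed-midnight-time",)
            report.add(vid, "missing-clock-time", "flagged")
        visits.append(EDVisit(
            participant_id=str(row[dialect.col("participant_id")]).strip(),
            visit_id=vid,
            arrival_dt=arrival,
            departure_dt=departure,
            departure_status=str(row[dialect.col("departure_status")]).strip(),
            campus=_opt(row, dialect, "campus"),
            visit_type=_opt(row, dialect, "visit_type"),
            referred_by=_opt(row, dialect, "referred_by"),
            diagnosis_codes=_diag(row, dialect),
            flags=flags,
        ))
    check_unique_ids([v.visit_id for v in visits], "visit")
    visits, report = validate_and_clean(visits, cleaning_policy, report=report)
    return visits, report


def read_episodes(
    source: str | Path,
    dialect: Dialect = VAED_LIKE,
    missing_time_policy: MissingTimePolicy = "impute-midnight",
    cleaning_policy: Policy = "strict",
) -> tuple[list[HospitalEpisode], CleaningReport]:
    """Read an admitted-episode CSV; assemble datetimes; validate and clean."""
    df = _read_rows(source, dialect, EPISODE_FIELDS)
    report = CleaningReport(n_input=len(df))
    episodes: list[HospitalEpisode] = []
    for idx, row in df.iterrows():
        eid = str(row[dialect.col("episode_id")]).strip()
        try:
            admission, h_imp = assemble_datetime(
                row[dialect.col("admission_date")], row[dialect.col("admission_time")],
                missing_time_policy, dialect)
            separation, s_imp = assemble_datetime(
                row[dialect.col("separation_date")], row[dialect.col("separation_time")],
                missing_time_policy, dialect)
        except RecordParseError as exc:
            raise RecordParseError(f"{source} row {idx} episode {eid!r}: {exc}") from None
        if admission is None or separation is None:
            report.add(eid, "missing-clock-time", "dropped")
            continue
        flags: tuple[str, ...] = ()
        if h_imp or s_imp:
            flags = ("imputed-midnight-time",)
            report.add(eid, "missing-clock-time", "flagged")
        episodes.append(HospitalEpisode(
            participant_id=str(row[dialect.col("participant_id")]).strip(),
            episode_id=eid,
            admission_dt=admission,
            separation_dt=separation,
            admission_type=str(row[dialect.col("admission_type")]).strip(),
            separation_mode=str(row[dialect.col("separation_mode")]).strip(),
            admission_source=_opt(row, dialect, "admission_source"),
            campus=_opt(row, dialect, "campus"),
            care_type=_opt(row, dialect, "care_type"),
            diagnosis_codes=_diag(row, dialect),
            flags=flags,
        ))
    check_unique_ids([e.episode_id for e in episodes], "episode")
    episodes, report = validate_and_clean(episodes, cleaning_policy, report=report)
    return episodes, report


# ---------------------------------------------------------------------------
# writers (round-trip safe: dates and times re-split into separate columns)

def _fmt(dt: datetime) -> tuple[str, str]:
    return dt.strftime("%Y-%m-%d"), dt.strftime("%H:%M")


def write_visits(visits: Sequence[EDVisit], path: str | Path,
                 dialect: Dialect = VEMD_LIKE) -> None:
    cols = [dialect.col(c) for c in VISIT_FIELDS + VISIT_OPTIONAL]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for v in visits:
            ad, at = _fmt(v.arrival_dt)
            dd, dt_ = _fmt(v.departure_dt)
            w.writerow([
                v.participant_id, v.visit_id, ad, at, dd, dt_,
                v.departure_status, v.campus, v.visit_type, v.referred_by,
                dialect.diagnosis_sep.join(v.diagnosis_codes),
            ])


def write_episodes(episodes: Sequence[HospitalEpisode], path: str | Path,
                   dialect: Dialect = VAED_LIKE) -> None:
    cols = [dialect.col(c) for c in EPISODE_FIELDS + EPISODE_OPTIONAL]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for e in episodes:
            hd, ht = _fmt(e.admission_dt)
            sd, st = _fmt(e.separation_dt)
            w.writerow([
                e.participant_id, e.episode_id, hd, ht, sd, st,
                e.admission_type, e.separation_mode, e.admission_source,
                e.campus, e.care_type,
                dialect.diagnosis_sep.join(e.diagnosis_codes),
            ])
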