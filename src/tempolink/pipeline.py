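"""End-to-end orchestration: clean -> chain -> link -> audit.

One run reads the two input tables, applies cleaning, builds transfer
chains, links visits to episodes, audits the result against the
disposition codes and writes a fixed output layout plus a manifest with
the full config snapshot and content hashes — identical inputs and
config give identical hashes.
"""

from __future__ import annotations

import csv
import hashlib
import json
from datetime import timedelta
from pathlib import Path

from pydantic import BaseModel, Field

from .chaining import ChainConfig, chain_episodes, chain_length_histogram
from .cleaning import Policy
from .codes import CodeMaps
from .io import (MissingTimePolicy, VAED_LIKE, VEMD_LIKE, read_episodes,
                 read_visits, write_episodes, write_visits)
from .linkage import LinkWindowConfig, LinkageResult, LinkedPair, link
from .metrics import (admission_type_crosstab, departure_status_crosstab,
                      summarize)
from .records import EDVisit, HospitalEpisode


class RunConfig(BaseModel):
    """Self-describing configuration for one pipeline run."""

    visits_path: str
    episodes_path: str
    out_dir: str
    code_maps_path: str | None = None
    link: LinkWindowConfig = Field(default_factory=LinkWindowConfig)
    chain: ChainConfig = Field(default_factory=ChainConfig)
    missing_time_policy: MissingTimePolicy = "impute-midnight"
    cleaning_policy: Policy = "strict"

    def code_maps(self) -> CodeMaps:
        if self.code_maps_path:
            return CodeMaps.from_yaml(self.code_maps_path)
        return CodeMaps()


class PipelineError(RuntimeError):
    """Stage-named pipeline failure."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


_LINKED_COLUMNS = [
    "participant_id", "visit_id", "arrival_dt", "departure_dt",
    "departure_status", "visit_campus", "episode_id", "admission_dt",
    "separation_dt", "admission_type", "separation_mode", "episode_campus",
    "care_type", "category", "delta_arrival_admission_min",
    "delta_departure_admission_min",
]

_DT = "%Y-%m-%d %H:%M"


def write_linked_wide(result: LinkageResult, path: str | Path) -> None:
    """One row per linked pair: ED fields + episode fields + category."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_LINKED_COLUMNS)
        for p in result.linked:
            v, e = p.visit, p.episode
            w.writerow([
                v.participant_id, v.visit_id,
                v.arrival_dt.strftime(_DT), v.departure_dt.strftime(_DT),
                v.departure_status, v.campus,
                e.episode_id, e.admission_dt.strftime(_DT),
                e.separation_dt.strftime(_DT), e.admission_type,
                e.separation_mode, e.campus, e.care_type, p.category,
                p.delta_arrival_admission, p.delta_departure_admission,
            ])


def write_chains_long(chains, labels: dict[str, str], path: str | Path) -> None:
    """Long format: one row per episode with chain id, position, label."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["chain_id", "position", "label", "participant_id",
                    "episode_id", "admission_dt", "separation_dt",
                    "separation_mode", "care_type"])
        for i, ch in enumerate(chains):
            for pos, e in enumerate(ch.episodes):
                w.writerow([
                    i, pos, labels[e.episode_id], e.participant_id,
                    e.episode_id, e.admission_dt.strftime(_DT),
                    e.separation_dt.strftime(_DT), e.separation_mode,
                    e.care_type,
                ])


def audit_report(result: LinkageResult, code_maps: CodeMaps) -> dict:
    """Summary + both expected-vs-found cross-tabs as one JSON object."""
    ds_tab, ds_props = departure_status_crosstab(result, code_maps)
    at_tab, at_props = admission_type_crosstab(result, code_maps)
    return {
        "summary": summarize(result).to_dict(),
        "departure_status_crosstab": {
            "cells": {"a": ds_tab.a, "b": ds_tab.b, "c": ds_tab.c, "d": ds_tab.d},
            "n_unmapped_excluded": len(ds_tab.excluded_unmapped),
            **ds_props,
        },
        "admission_type_crosstab": {
            "cells": {"a": at_tab.a, "b": at_tab.b, "c": at_tab.c, "d": at_tab.d},
            "n_unmapped_excluded": len(at_tab.excluded_unmapped),
            **at_props,
        },
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    for name, p in (("visits", config.visits_path),
                    ("episodes", config.episodes_path)):
        if not Path(p).exists():
            raise PipelineError("input", f"{name} file not found: {p}")
    out.mkdir(parents=True, exist_ok=True)
    code_maps = config.code_maps()

    try:
        visits, vreport = read_visits(
            config.visits_path, VEMD_LIKE, config.missing_time_policy,
            config.cleaning_policy)
        episodes, ereport = read_episodes(
            config.episodes_path, VAED_LIKE, config.missing_time_policy,
            config.cleaning_policy)
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError("read", str(exc)) from exc

    chains, labels, chain_report = chain_episodes(episodes, code_maps, config.chain)
    result = link(visits, episodes, config.link, code_maps, config.chain)
    audit = audit_report(result, code_maps)

    write_visits(visits, out / "cleaned_visits.csv")
    write_episodes(episodes, out / "cleaned_episodes.csv")
    write_chains_long(chains, labels, out / "chains_long.csv")
    write_linked_wide(result, out / "linked_wide.csv")
    write_visits(result.unlinked_visits, out / "unlinked_visits.csv")
    write_episodes(
        result.unlinked_episodes + result.continuation_episodes,
        out / "unlinked_episodes.csv")
    (out / "cleaning_visits.json").write_text(vreport.to_json(), encoding="utf-8")
    (out / "cleaning_episodes.json").write_text(ereport.to_json(), encoding="utf-8")
    (out / "audit.json").write_text(
        json.dumps(audit, indent=2, sort_keys=True), encoding="utf-8")

    artefacts = sorted(p.name for p in out.glob("*") if p.name != "manifest.json")
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "chain_length_histogram": {
            str(k): v for k, v in chain_length_histogram(chains).items()},
        "chaining_quality": {
            "n_unmapped_separation_modes": len(chain_report.unmapped_separation_modes),
            "n_overlapping_in_chain": len(chain_report.overlapping_in_chain),
            "n_dangling_transfers": len(chain_report.dangling_transfers),
        },
        "summary": result.summary_counts(),
        "hashes": {name: _sha256(out / name) for name in artefacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest


def load_result(out_dir: str | Path) -> LinkageResult:
    """Rebuild a LinkageResult from a run directory (for re-auditing)."""
    from datetime import datetime

    out = Path(out_dir)
    linked: list[LinkedPair] = []
    with open(out / "linked_wide.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            v = EDVisit(
                participant_id=row["participant_id"], visit_id=row["visit_id"],
                arrival_dt=datetime.strptime(row["arrival_dt"], _DT),
                departure_dt=datetime.strptime(row["departure_dt"], _DT),
                departure_status=row["departure_status"],
                campus=row["visit_campus"])
            e = HospitalEpisode(
                participant_id=row["participant_id"],
                episode_id=row["episode_id"],
                admission_dt=datetime.strptime(row["admission_dt"], _DT),
                separation_dt=datetime.strptime(row["separation_dt"], _DT),
                admission_type=row["admission_type"],
                separation_mode=row["separation_mode"],
                campus=row["episode_campus"], care_type=row["care_type"])
            linked.append(LinkedPair(
                v, e, row["category"],
                int(row["delta_arrival_admission_min"]),
                int(row["delta_departure_admission_min"])))
    unlinked_visits, _ = read_visits(out / "unlinked_visits.csv")
    unlinked_episodes, _ = read_episodes(out / "unlinked_episodes.csv")
    return LinkageResult(
        linked=tuple(linked),
        unlinked_visits=tuple(unlinked_visits),
        unlinked_episodes=tuple(unlinked_episodes),
        continuation_episodes=(),
        chains=(),
        config=LinkWindowConfig(),
    )
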