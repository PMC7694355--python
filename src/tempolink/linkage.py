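"""Temporal linkage of ED visits to hospital admission episodes.

A visit (arrival A, departure D) and an episode (admission H, separation
S) for the same person form a *true link* when their timestamps satisfy
one of six temporal relationships:

========  =====================================================
category  definition (first match in precedence order wins)
========  =====================================================
L1        H = A  (admission time equal to ED arrival)
L2        H = D  (admission time equal to ED departure)
L4        A < H and S < D  (admission and discharge nested
          inside the ED stay)
L3        A < H < D  (admission at some point within the stay)
L5        0 < H - D <= post-departure window (default 24 h)
L6        0 < A - H <= pre-arrival window (default 24 h),
          requiring A < S (arrival before hospital separation)
========  =====================================================

Candidate pairs are the within-person Cartesian product of visits and
episodes.  Classified candidates are pruned to a one-to-one matching by
retaining, greedily, the pairs with the shortest absolute arrival-to-
admission difference |H - A|; ties break on (visit_id, episode_id) so a
run is deterministic.  By default continuation episodes of a transfer
chain are excluded from candidate generation, so ED visits link to index
admissions only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, field_validator

from .chaining import ChainConfig, EpisodeChain, chain_episodes
from .codes import CodeMaps
from .records import EDVisit, HospitalEpisode, group_by_participant

CATEGORIES = ("L1", "L2", "L3", "L4", "L5", "L6")
DEFAULT_PRECEDENCE = ("L1", "L2", "L4", "L3", "L5", "L6")


class LinkWindowConfig(BaseModel):
    """Windows and precedence for the six link categories."""

    post_departure_window: timedelta = Field(default=timedelta(hours=24))
    pre_arrival_window: timedelta = Field(default=timedelta(hours=24))
    category_precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    link_after_chaining: bool = True

    model_config = {"frozen": True}

    @field_validator("post_departure_window", "pre_arrival_window")
    @classmethod
    def _nonneg(cls, v: timedelta) -> timedelta:
        if v < timedelta(0):
            raise ValueError("windows must be >= 0")
        return v

    @field_validator("category_precedence")
    @classmethod
    def _perm(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if sorted(v) != sorted(CATEGORIES):
            raise ValueError("category_precedence must permute L1..L6")
        return v


@dataclass(frozen=True)
class CandidatePair:
    """A within-person (visit, episode) pairing with signed offsets."""

    participant_id: str
    visit_id: str
    episode_id: str
    delta_arrival_admission: int  # minutes, H - A
    delta_departure_admission: int  # minutes, H - D
    category: str | None = None


def _minutes(td: timedelta) -> int:
    return int(td.total_seconds() // 60)


def classify_pair(
    arrival: datetime,
    departure: datetime,
    admission: datetime,
    separation: datetime,
    config: LinkWindowConfig = LinkWindowConfig(),
) -> str | None:
    """Assign the first matching link category, or None.

    Preconditions: minute-resolution timestamps with A <= D and H <= S.
    """
    if departure < arrival or separation < admission:
        raise ValueError(
            "invalid pair: requires arrival <= departure and admission <= separation"
        )
    a, d, h, s = arrival, departure, admission, separation
    for cat in config.category_precedence:
        if cat == "L1" and h == a:
            return "L1"
        if cat == "L2" and h == d:
            return "L2"
        if cat == "L4" and a < h and s < d:
            return "L4"
        if cat == "L3" and a < h < d:
            return "L3"
        if cat == "L5" and timedelta(0) < h - d <= config.post_departure_window:
            return "L5"
        if cat == "L6" and timedelta(0) < a - h <= config.pre_arrival_window and a < s:
            return "L6"
    return None


def candidate_pairs(
    visits: Sequence[EDVisit],
    episodes: Sequence[HospitalEpisode],
) -> list[CandidatePair]:
    """Every within-person (visit, episode) combination, offsets in minutes."""
    by_pid = group_by_participant(episodes)
    pairs: list[CandidatePair] = []
    for v in visits:
        for e in by_pid.get(v.participant_id, ()):
            pairs.append(CandidatePair(
                participant_id=v.participant_id,
                visit_id=v.visit_id,
                episode_id=e.episode_id,
                delta_arrival_admission=_minutes(e.admission_dt - v.arrival_dt),
                delta_departure_admission=_minutes(e.admission_dt - v.departure_dt),
            ))
    return pairs


def classify_candidates(
    pairs: Iterable[CandidatePair],
    visits: Sequence[EDVisit],
    episodes: Sequence[HospitalEpisode],
    config: LinkWindowConfig = LinkWindowConfig(),
) -> list[CandidatePair]:
    """Classify candidates, keeping only those matching some category."""
    vmap = {v.visit_id: v for v in visits}
    emap = {e.episode_id: e for e in episodes}
    out: list[CandidatePair] = []
    for p in pairs:
        v, e = vmap[p.visit_id], emap[p.episode_id]
        cat = classify_pair(
            v.arrival_dt, v.departure_dt, e.admission_dt, e.separation_dt, config
        )
        if cat is not None:
            out.append(CandidatePair(
                p.participant_id, p.visit_id, p.episode_id,
                p.delta_arrival_admission, p.delta_departure_admission, cat,
            ))
    return out


def prune_and_deduplicate(candidates: Sequence[CandidatePair]) -> list[CandidatePair]:
    """Greedy 1:1 matching by shortest |H - A|.

    Candidates are sorted by (|delta|, visit_id, episode_id) and accepted
    iff neither endpoint is already matched.  Deterministic for fixed
    input; each visit and each episode appears in at most one retained
    pair.
    """
    if any(p.category is None for p in candidates):
        raise ValueError("all candidates must be classified before pruning")
    ordered = sorted(
        candidates,
        key=lambda p: (abs(p.delta_arrival_admission), p.visit_id, p.episode_id),
    )
    used_v: set[str] = set()
    used_e: set[str] = set()
    kept: list[CandidatePair] = []
    for p in ordered:
        if p.visit_id in used_v or p.episode_id in used_e:
            continue
        used_v.add(p.visit_id)
        used_e.add(p.episode_id)
        kept.append(p)
    return kept


@dataclass(frozen=True)
class LinkedPair:
    visit: EDVisit
    episode: HospitalEpisode
    category: str
    delta_arrival_admission: int
    delta_departure_admission: int


@dataclass(frozen=True)
class LinkageResult:
    """Partition of the inputs into linked pairs and unlinked records.

    ``unlinked_episodes`` covers the episodes eligible for linking; when
    linking ran after chaining, continuation episodes were ineligible and
    are listed separately in ``continuation_episodes``.
    """

    linked: tuple[LinkedPair, ...]
    unlinked_visits: tuple[EDVisit, ...]
    unlinked_episodes: tuple[HospitalEpisode, ...]
    continuation_episodes: tuple[HospitalEpisode, ...]
    chains: tuple[EpisodeChain, ...]
    config: LinkWindowConfig

    @property
    def n_visits(self) -> int:
        return len(self.linked) + len(self.unlinked_visits)

    @property
    def n_episodes(self) -> int:
        """All input episodes, continuations included."""
        return (
            len(self.linked)
            + len(self.unlinked_episodes)
            + len(self.continuation_episodes)
        )

    @property
    def all_visits(self) -> tuple[EDVisit, ...]:
        return tuple(p.visit for p in self.linked) + self.unlinked_visits

    @property
    def all_episodes(self) -> tuple[HospitalEpisode, ...]:
        return (
            tuple(p.episode for p in self.linked)
            + self.unlinked_episodes
            + self.continuation_episodes
        )

    def summary_counts(self) -> dict[str, int]:
        counts = {
            "n_visits": self.n_visits,
            "n_episodes": self.n_episodes,
            "n_linked": len(self.linked),
            "n_unlinked_visits": len(self.unlinked_visits),
            "n_unlinked_episodes": len(self.unlinked_episodes),
            "n_continuation_episodes": len(self.continuation_episodes),
        }
        for cat in CATEGORIES:
            counts[f"n_{cat}"] = sum(1 for p in self.linked if p.category == cat)
        return counts

    def to_json(self) -> str:
        """Canonical serialisation of the matching (byte-stable)."""
        payload = {
            "config": {
                "post_departure_window_min": _minutes(self.config.post_departure_window),
                "pre_arrival_window_min": _minutes(self.config.pre_arrival_window),
                "category_precedence": list(self.config.category_precedence),
                "link_after_chaining": self.config.link_after_chaining,
            },
            "summary": self.summary_counts(),
            "linked": [
                [p.visit.visit_id, p.episode.episode_id, p.category,
                 p.delta_arrival_admission, p.delta_departure_admission]
                for p in sorted(self.linked, key=lambda p: p.visit.visit_id)
            ],
            "unlinked_visits": sorted(v.visit_id for v in self.unlinked_visits),
            "unlinked_episodes": sorted(e.episode_id for e in self.unlinked_episodes),
            "continuation_episodes": sorted(
                e.episode_id for e in self.continuation_episodes
            ),
        }
        return json.dumps(payload, sort_keys=True)


def link(
    visits: Sequence[EDVisit],
    episodes: Sequence[HospitalEpisode],
    config: LinkWindowConfig = LinkWindowConfig(),
    code_maps: CodeMaps = CodeMaps(),
    chain_config: ChainConfig = ChainConfig(),
) -> LinkageResult:
    """Run the full linkage pass and partition the inputs.

    With ``link_after_chaining`` (default) continuation episodes of
    transfer chains are excluded from candidate generation, so a chain's
    index admission is the only possible link target for an ED visit.
    """
    if config.link_after_chaining:
        chains, labels, _ = chain_episodes(episodes, code_maps, chain_config)
        eligible = [e for e in episodes if labels[e.episode_id] == "index"]
        continuations = tuple(
            e for e in episodes if labels[e.episode_id] == "continuation"
        )
    else:
        chains, continuations = [], ()
        eligible = list(episodes)

    cands = candidate_pairs(visits, eligible)
    classified = classify_candidates(cands, visits, eligible, config)
    kept = prune_and_deduplicate(classified)

    vmap = {v.visit_id: v for v in visits}
    emap = {e.episode_id: e for e in eligible}
    linked = tuple(
        LinkedPair(vmap[p.visit_id], emap[p.episode_id], p.category,
                   p.delta_arrival_admission, p.delta_departure_admission)
        for p in sorted(kept, key=lambda p: p.visit_id)
    )
    linked_v = {p.visit.visit_id for p in linked}
    linked_e = {p.episode.episode_id for p in linked}
    return LinkageResult(
        linked=linked,
        unlinked_visits=tuple(v for v in visits if v.visit_id not in linked_v),
        unlinked_episodes=tuple(
            e for e in eligible if e.episode_id not in linked_e
        ),
        continuation_episodes=continuations,
        chains=tuple(chains),
        config=config,
    )
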