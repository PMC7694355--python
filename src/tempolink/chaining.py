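"""Continuous episodes of care: chaining sequential admitted episodes.

One total hospital stay can generate several admitted-episode records
when the patient is transferred between care-types or campuses before
final discharge.  A subsequent episode is chained to its predecessor
when (a) the predecessor's separation mode indicates a *planned*
transfer of care, and (b) the episode's admission falls within the chain
window (default 24 h) of the predecessor's anchor timestamp.  Requiring
a planned-transfer code keeps unplanned re-admissions within 24 h out of
the chain — those are distinct clinical pathways, not continuations.

The first episode of each chain is the *index admission*; later episodes
are *continuations* and are stored long-format under their index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Literal, Sequence

from pydantic import BaseModel, Field

from .codes import CodeMaps
from .records import HospitalEpisode, group_by_participant


class ChainConfig(BaseModel):
    """Parameters of the continuous-episode-of-care rule."""

    chain_window: timedelta = Field(default=timedelta(hours=24))
    anchor: Literal["separation_of_predecessor", "admission_of_predecessor"] = (
        "separation_of_predecessor"
    )
    max_chain_length: int | None = None

    model_config = {"frozen": True}

    def model_post_init(self, __context) -> None:
        if self.chain_window < timedelta(0):
            raise ValueError("chain_window must be >= 0")


@dataclass(frozen=True)
class EpisodeChain:
    """An index admission plus its ordered continuation episodes."""

    index_episode: HospitalEpisode
    continuations: tuple[HospitalEpisode, ...] = ()

    @property
    def episodes(self) -> tuple[HospitalEpisode, ...]:
        return (self.index_episode,) + self.continuations

    @property
    def stay_start(self) -> datetime:
        return self.index_episode.admission_dt

    @property
    def stay_end(self) -> datetime:
        return self.episodes[-1].separation_dt

    def __len__(self) -> int:
        return 1 + len(self.continuations)


@dataclass
class ChainingReport:
    """Data-quality side channel of the chaining pass."""

    unmapped_separation_modes: list[tuple[str, str]] = field(default_factory=list)
    overlapping_in_chain: list[str] = field(default_factory=list)
    dangling_transfers: list[str] = field(default_factory=list)  # planned transfer, no successor in window


def _sort_key(e: HospitalEpisode):
    return (e.admission_dt, e.separation_dt, e.episode_id)


def chain_episodes(
    episodes: Sequence[HospitalEpisode],
    code_maps: CodeMaps = CodeMaps(),
    config: ChainConfig = ChainConfig(),
) -> tuple[list[EpisodeChain], dict[str, str], ChainingReport]:
    """Partition episodes into chains; label each 'index' or 'continuation'.

    Episodes are processed per participant in (admission, separation, id)
    order.  An episode joins the open chain iff the previous episode's
    separation mode is a planned-transfer code and its admission is no
    later than the anchor timestamp plus the chain window; otherwise it
    opens a new chain as an index admission.  Every episode receives
    exactly one label.
    """
    chains: list[EpisodeChain] = []
    labels: dict[str, str] = {}
    report = ChainingReport()

    for pid in sorted(group_by_participant(episodes)):
        ordered = sorted(group_by_participant(episodes)[pid], key=_sort_key)
        current: list[HospitalEpisode] = []
        for ep in ordered:
            if not code_maps.is_known_separation(ep.separation_mode):
                report.unmapped_separation_modes.append(
                    (ep.episode_id, ep.separation_mode)
                )
            if current:
                prev = current[-1]
                anchor = (
                    prev.separation_dt
                    if config.anchor == "separation_of_predecessor"
                    else prev.admission_dt
                )
                within = ep.admission_dt <= anchor + config.chain_window
                transfer = code_maps.is_transfer_separation(prev.separation_mode)
                room = (
                    config.max_chain_length is None
                    or len(current) < config.max_chain_length
                )
                if transfer and within and room:
                    if ep.admission_dt < prev.separation_dt:
                        report.overlapping_in_chain.append(ep.episode_id)
                    current.append(ep)
                    continue
                if transfer and not within:
                    report.dangling_transfers.append(prev.episode_id)
            if current:
                chains.append(EpisodeChain(current[0], tuple(current[1:])))
            current = [ep]
        if current:
            if code_maps.is_transfer_separation(current[-1].separation_mode):
                report.dangling_transfers.append(current[-1].episode_id)
            chains.append(EpisodeChain(current[0], tuple(current[1:])))

    for ch in chains:
        labels[ch.index_episode.episode_id] = "index"
        for cont in ch.continuations:
            labels[cont.episode_id] = "continuation"
    return chains, labels, report


def chain_length_histogram(chains: Sequence[EpisodeChain]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for ch in chains:
        hist[len(ch)] = hist.get(len(ch), 0) + 1
    return dict(sorted(hist.items()))
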