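"""Audit analyses: cross-tabs, summary proportions and lag profiles.

The cross-tabs ask whether each standalone dataset's disposition code
would have predicted the link that temporal matching actually found:
does an admission-suggesting ED departure status coincide with a linked
admission, and does an "emergency via this ED" admission type coincide
with a linked preceding visit?  Percentages are rounded half-up to
integer percent to match administrative reporting conventions; nonzero
shares under 0.5% render as "<1%".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import timedelta
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .chaining import ChainConfig, EpisodeChain
from .codes import CodeMaps
from .linkage import CATEGORIES, LinkWindowConfig, LinkageResult
from .records import EDVisit, HospitalEpisode


def pct_half_up(numerator: float, denominator: float) -> int | None:
    """Integer percentage with half-up rounding; None when undefined."""
    if denominator == 0:
        return None
    return int(
        (Decimal(numerator) / Decimal(denominator) * 100).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )


def format_pct(numerator: float, denominator: float) -> str:
    """Render a share as e.g. '17%', with '<1%' for nonzero shares < 0.5%."""
    if denominator == 0:
        return "n/a"
    if numerator > 0 and numerator / denominator < 0.005:
        return "<1%"
    return f"{pct_half_up(numerator, denominator)}%"


@dataclass(frozen=True)
class CrossTab2x2:
    """rows = code-based expectation, columns = link found yes/no."""

    a: int  # expected,    link found
    b: int  # expected,    no link
    c: int  # not expected, link found
    d: int  # not expected, no link
    row_labels: tuple[str, str] = ("expected", "not expected")
    col_labels: tuple[str, str] = ("link found", "no link")
    excluded_unmapped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cross-tab cells must be >= 0")

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_csv(self) -> str:
        lines = [
            "," + ",".join(self.col_labels) + ",total",
            f"{self.row_labels[0]},{self.a},{self.b},{self.a + self.b}",
            f"{self.row_labels[1]},{self.c},{self.d},{self.c + self.d}",
            f"total,{self.a + self.c},{self.b + self.d},{self.total}",
        ]
        return "\n".join(lines) + "\n"


def departure_status_crosstab(
    result: LinkageResult, code_maps: CodeMaps = CodeMaps()
) -> tuple[CrossTab2x2, dict[str, int | None]]:
    """Expected-vs-found links from the ED departure-status codes.

    Returns the 2x2 table over visits plus agreement proportions:
    ``linked_agreement_pct`` — share of linked visits whose departure
    status suggested an admission; ``unlinked_agreement_pct`` — share of
    unlinked visits whose status suggested no admission.
    """
    linked_ids = {p.visit.visit_id for p in result.linked}
    cells = {("admission_expected", True): 0, ("admission_expected", False): 0,
             ("no_admission", True): 0, ("no_admission", False): 0}
    unmapped: list[str] = []
    for v in result.all_visits:
        grp = code_maps.departure_status_group(v.departure_status)
        if grp == "unmapped":
            unmapped.append(v.visit_id)
            continue
        cells[(grp, v.visit_id in linked_ids)] += 1
    tab = CrossTab2x2(
        a=cells[("admission_expected", True)],
        b=cells[("admission_expected", False)],
        c=cells[("no_admission", True)],
        d=cells[("no_admission", False)],
        row_labels=("admission expected", "admission not expected"),
        col_labels=("linked", "unlinked"),
        excluded_unmapped=tuple(unmapped),
    )
    props = {
        "linked_agreement_pct": pct_half_up(tab.a, tab.a + tab.c),
        "unlinked_agreement_pct": pct_half_up(tab.d, tab.b + tab.d),
    }
    return tab, props


def admission_type_crosstab(
    result: LinkageResult, code_maps: CodeMaps = CodeMaps()
) -> tuple[CrossTab2x2, dict[str, int | None]]:
    """Expected-vs-found links from the admission-type codes.

    Covers all episode records (continuations are unlinked by
    construction).  Reports the found-link rate among episodes whose
    admission type explicitly names a preceding ED visit.
    """
    linked_ids = {p.episode.episode_id for p in result.linked}
    cells = {("ed_expected", True): 0, ("ed_expected", False): 0,
             ("uncertain", True): 0, ("uncertain", False): 0}
    unmapped: list[str] = []
    for e in result.all_episodes:
        grp = code_maps.admission_type_group(e.admission_type)
        if grp == "unmapped":
            unmapped.append(e.episode_id)
            continue
        cells[(grp, e.episode_id in linked_ids)] += 1
    tab = CrossTab2x2(
        a=cells[("ed_expected", True)],
        b=cells[("ed_expected", False)],
        c=cells[("uncertain", True)],
        d=cells[("uncertain", False)],
        row_labels=("preceding ED visit expected", "preceding ED visit uncertain"),
        col_labels=("linked", "unlinked"),
        excluded_unmapped=tuple(unmapped),
    )
    props = {
        "found_link_rate_ed_expected_pct": pct_half_up(tab.a, tab.a + tab.b),
    }
    return tab, props


@dataclass(frozen=True)
class SummaryReport:
    n_visits: int
    n_episodes: int
    n_linked: int
    pct_visits_linked: int | None
    pct_episodes_linked: int | None
    n_complete_dataset: int
    category_histogram: dict[str, int]
    category_pct: dict[str, str]
    lag_stats: dict[str, dict[str, float | int | None]] = field(default_factory=dict)
    chain_length_histogram: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_visits": self.n_visits,
            "n_episodes": self.n_episodes,
            "n_linked": self.n_linked,
            "pct_visits_linked": self.pct_visits_linked,
            "pct_episodes_linked": self.pct_episodes_linked,
            "n_complete_dataset": self.n_complete_dataset,
            "category_histogram": self.category_histogram,
            "category_pct": self.category_pct,
            "lag_stats": self.lag_stats,
            "chain_length_histogram": {
                str(k): v for k, v in self.chain_length_histogram.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def summarize_counts(
    n_visits: int,
    n_episodes: int,
    n_linked: int,
    category_histogram: dict[str, int] | None = None,
) -> SummaryReport:
    """Summary proportions from bare counts.

    The complete linked dataset holds each linked pair once, so its size
    is n_visits + n_episodes - n_linked.
    """
    hist = {c: int((category_histogram or {}).get(c, 0)) for c in CATEGORIES}
    if category_histogram is not None and sum(hist.values()) != n_linked:
        raise ValueError("category histogram must sum to n_linked")
    pct = {c: format_pct(hist[c], n_linked) for c in CATEGORIES}
    if n_linked == 0:
        pct_v = 0 if n_visits else None
        pct_e = 0 if n_episodes else None
    else:
        pct_v = pct_half_up(n_linked, n_visits)
        pct_e = pct_half_up(n_linked, n_episodes)
    return SummaryReport(
        n_visits=n_visits,
        n_episodes=n_episodes,
        n_linked=n_linked,
        pct_visits_linked=pct_v,
        pct_episodes_linked=pct_e,
        n_complete_dataset=n_visits + n_episodes - n_linked,
        category_histogram=hist,
        category_pct=pct,
    )


def _lag_stats(result: LinkageResult) -> dict[str, dict]:
    """Per-category |H - A| quantiles plus the short-lag shares that
    matter clinically: L5 links admitted within 2 h of ED departure and
    L6 links with at most an 11-minute arrival/admission discrepancy."""
    stats: dict[str, dict] = {}
    for cat in CATEGORIES:
        lags = [abs(p.delta_arrival_admission) for p in result.linked
                if p.category == cat]
        if not lags:
            stats[cat] = {"n": 0}
            continue
        q = np.percentile(lags, [50, 90], method="nearest")
        stats[cat] = {
            "n": len(lags),
            "abs_lag_min_median": float(q[0]),
            "abs_lag_min_p90": float(q[1]),
        }
    l5 = [p.delta_departure_admission for p in result.linked if p.category == "L5"]
    if l5:
        stats["L5"]["pct_within_2h_of_departure"] = pct_half_up(
            sum(1 for x in l5 if 0 < x <= 120), len(l5)
        )
    l6 = [-p.delta_arrival_admission for p in result.linked if p.category == "L6"]
    if l6:
        stats["L6"]["pct_within_11min_of_arrival"] = pct_half_up(
            sum(1 for x in l6 if 0 < x <= 11), len(l6)
        )
    return stats


def summarize(
    result: LinkageResult, chains: Sequence[EpisodeChain] | None = None
) -> SummaryReport:
    """Full summary of a linkage run (counts, shares, lags, chains)."""
    counts = result.summary_counts()
    hist = {c: counts[f"n_{c}"] for c in CATEGORIES}
    base = summarize_counts(
        counts["n_visits"], counts["n_episodes"], counts["n_linked"], hist
    )
    chain_hist: dict[int, int] = {}
    for ch in chains if chains is not None else result.chains:
        chain_hist[len(ch)] = chain_hist.get(len(ch), 0) + 1
    return SummaryReport(
        **{**base.__dict__,
           "lag_stats": _lag_stats(result),
           "chain_length_histogram": dict(sorted(chain_hist.items()))}
    )


def window_sensitivity(
    visits: Sequence[EDVisit],
    episodes: Sequence[HospitalEpisode],
    windows: Sequence[timedelta],
    config: LinkWindowConfig = LinkWindowConfig(),
    code_maps: CodeMaps = CodeMaps(),
    chain_config: ChainConfig = ChainConfig(),
) -> list[dict]:
    """Re-run linkage over a grid of window widths.

    Each grid value replaces both the post-departure (L5) and
    pre-arrival (L6) windows; rows are ordered by window width and carry
    the classified-candidate count, the retained-link count and the
    per-category link counts.  Candidate counts are non-decreasing in
    window width.
    """
    from .linkage import candidate_pairs, classify_candidates, link

    rows: list[dict] = []
    for w in sorted(windows):
        if w < timedelta(0):
            raise ValueError("windows must be >= 0")
        cfg = config.model_copy(
            update={"post_departure_window": w, "pre_arrival_window": w}
        )
        res = link(visits, episodes, cfg, code_maps, chain_config)
        eligible = [e for e in episodes
                    if e.episode_id not in
                    {c.episode_id for c in res.continuation_episodes}]
        n_cand = len(classify_candidates(
            candidate_pairs(visits, eligible), visits, eligible, cfg
        ))
        row = {
            "window_hours": w.total_seconds() / 3600.0,
            "n_candidates": n_cand,
            "n_linked": len(res.linked),
        }
        for c in CATEGORIES:
            row[f"n_{c}"] = res.summary_counts()[f"n_{c}"]
        rows.append(row)
    return rows
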