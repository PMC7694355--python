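"""Link-category classification, candidate generation and 1:1 pruning."""

from dataclasses import replace
from datetime import datetime, timedelta

import pytest
from hypothesis import given, settings, strategies as st

from tempolink.cleaning import validate_and_clean
from tempolink.linkage import (CATEGORIES, LinkWindowConfig, candidate_pairs,
                               classify_candidates, classify_pair, link,
                               prune_and_deduplicate)
from tempolink.simulate import SimConfig, generate

from conftest import make_episode, make_visit

T0 = datetime(2010, 3, 1, 10, 0)  # reference ED arrival


def ts(minutes: float) -> datetime:
    return T0 + timedelta(minutes=minutes)


class TestClassifyPair:
    # A = 10:00, D = 14:30 throughout (270-minute ED stay)
    D = 270

    @pytest.mark.parametrize(
        "h, s, expected",
        [
            (0, 4 * 1440, "L1"),          # admission equal to ED arrival
            (270, 2 * 1440, "L2"),        # admission equal to ED departure
            (135, 2 * 1440, "L3"),        # admission within the stay, S >= D
            (60, 180, "L4"),              # admission and discharge nested in the stay
            (270 + 22 * 60 + 30, 5000, "L5"),  # 22.5 h after departure
            (270 + 25 * 60, 5000, None),  # 25 h after departure: outside the window
            (270 + 24 * 60, 5000, "L5"),  # inclusive 24-h bound
            (-11, 1440, "L6"),            # 11 min before ED arrival, S > A
            (-1440, 2 * 1440, "L6"),      # inclusive 24-h bound
            (-1441, 2 * 1440, None),      # beyond the pre-arrival window
            (-60, -30, None),             # separation before ED arrival: L6 excluded
        ],
    )
    def test_category_definitions(self, h, s, expected):
        got = classify_pair(T0, ts(self.D), ts(h), ts(s))
        assert got == expected

    def test_nested_stay_takes_l4_over_l3(self):
        # H inside the stay *and* S < D: precedence assigns L4, not L3
        assert classify_pair(T0, ts(self.D), ts(60), ts(180)) == "L4"
        assert classify_pair(T0, ts(self.D), ts(60), ts(self.D)) == "L3"

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(ts(60), T0, ts(0), ts(10))
        with pytest.raises(ValueError):
            classify_pair(T0, ts(60), ts(10), ts(0))

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        d=st.integers(0, 3000), h=st.integers(-3000, 6000),
        los=st.integers(0, 6000),
    )
    def test_exactly_one_label_per_quadruple(self, d, h, los):
        """The precedence order makes the six categories a partition:
        every quadruple gets exactly one label or none, stably."""
        got = [classify_pair(T0, ts(d), ts(h), ts(h + los)) for _ in range(2)]
        assert got[0] == got[1]
        assert got[0] in (None,) + CATEGORIES

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        d=st.integers(0, 3000), h=st.integers(-3000, 6000),
        los=st.integers(0, 6000), w1=st.integers(0, 2880), w2=st.integers(0, 2880),
    )
    def test_window_monotonicity(self, d, h, los, w1, w2):
        """Enlarging either window never unclassifies a candidate."""
        small = LinkWindowConfig(
            post_departure_window=timedelta(minutes=min(w1, w2)),
            pre_arrival_window=timedelta(minutes=min(w1, w2)))
        big = LinkWindowConfig(
            post_departure_window=timedelta(minutes=max(w1, w2)),
            pre_arrival_window=timedelta(minutes=max(w1, w2)))
        if classify_pair(T0, ts(d), ts(h), ts(h + los), small) is not None:
            assert classify_pair(T0, ts(d), ts(h), ts(h + los), big) is not None


class TestCandidatePairs:
    def test_within_participant_cartesian(self):
        visits = [make_visit(vid=f"V{i}") for i in range(2)]
        episodes = [make_episode(eid=f"E{i}") for i in range(3)]
        assert len(candidate_pairs(visits, episodes)) == 6

    def test_visits_only_yield_nothing(self):
        assert candidate_pairs([make_visit()], []) == []

    def test_no_cross_participant_pairs(self):
        visits = [make_visit(pid="P1", vid="V1"), make_visit(pid="P1", vid="V2"),
                  make_visit(pid="P2", vid="V3")]
        episodes = [make_episode(pid="P1", eid="E1"),
                    make_episode(pid="P2", eid="E2"),
                    make_episode(pid="P2", eid="E3")]
        pairs = candidate_pairs(visits, episodes)
        assert len(pairs) == 2 + 2
        assert all(p.participant_id in ("P1", "P2") for p in pairs)

    def test_deltas_in_signed_minutes(self):
        v = make_visit(arrival="2010-03-01 10:00", los_min=270)
        e = make_episode(admission="2010-03-01 09:49")
        (p,) = candidate_pairs([v], [e])
        assert p.delta_arrival_admission == -11
        assert p.delta_departure_admission == -281


def brute_force_dedup(candidates):
    """Independent oracle: repeatedly select, from the full remaining
    list, the globally best (|delta|, visit_id, episode_id) pair whose
    endpoints are both free; accept it; repeat until none remain."""
    remaining = list(candidates)
    accepted = []
    used_v, used_e = set(), set()
    while True:
        free = [p for p in remaining
                if p.visit_id not in used_v and p.episode_id not in used_e]
        if not free:
            return accepted
        best = min(free, key=lambda p: (abs(p.delta_arrival_admission),
                                        p.visit_id, p.episode_id))
        accepted.append(best)
        used_v.add(best.visit_id)
        used_e.add(best.episode_id)
        remaining.remove(best)


class TestPruneAndDeduplicate:
    def _classified(self, visits, episodes):
        return classify_candidates(candidate_pairs(visits, episodes),
                                   visits, episodes)

    def test_shortest_absolute_difference_retained(self):
        v = make_visit(vid="V1", arrival="2010-03-01 10:00", los_min=600)
        e_near = make_episode(eid="E1", admission="2010-03-01 10:05")
        e_far = make_episode(eid="E2", admission="2010-03-01 15:00")
        kept = prune_and_deduplicate(self._classified([v], [e_near, e_far]))
        assert [(p.visit_id, p.episode_id) for p in kept] == [("V1", "E1")]

    def test_empty_candidates(self):
        assert prune_and_deduplicate([]) == []

    def test_tie_broken_by_visit_id(self):
        v1 = make_visit(vid="V1", arrival="2010-03-01 10:00", los_min=60)
        v2 = make_visit(vid="V2", arrival="2010-03-01 10:20", los_min=60)
        e = make_episode(eid="E1", admission="2010-03-01 10:10")
        kept = prune_and_deduplicate(self._classified([v1, v2], [e]))
        assert [(p.visit_id, p.episode_id) for p in kept] == [("V1", "E1")]

    def test_unclassified_candidates_rejected(self):
        pairs = candidate_pairs([make_visit()], [make_episode()])
        with pytest.raises(ValueError):
            prune_and_deduplicate(pairs)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        n_v=st.integers(1, 6), n_e=st.integers(1, 6),
        arrivals=st.lists(st.integers(0, 5000), min_size=6, max_size=6),
        admissions=st.lists(st.integers(-1000, 7000), min_size=6, max_size=6),
    )
    def test_greedy_equals_brute_force_oracle(self, n_v, n_e, arrivals, admissions):
        visits = [replace(make_visit(vid=f"V{i}"),
                          arrival_dt=ts(a), departure_dt=ts(a + 240))
                  for i, a in zip(range(n_v), arrivals)]
        episodes = [replace(make_episode(eid=f"E{i}"),
                            admission_dt=ts(h), separation_dt=ts(h + 2880))
                    for i, h in zip(range(n_e), admissions)]
        classified = self._classified(visits, episodes)
        got = prune_and_deduplicate(classified)
        want = brute_force_dedup(classified)
        assert [(p.visit_id, p.episode_id) for p in got] == \
               [(p.visit_id, p.episode_id) for p in want]


class TestLink:
    def test_single_pair_links_l3(self):
        v = make_visit()
        e = make_episode()  # admitted two hours into a 4.5-hour stay
        res = link([v], [e])
        assert len(res.linked) == 1 and res.linked[0].category == "L3"
        assert res.unlinked_visits == () and res.unlinked_episodes == ()

    def test_lone_visit_stays_unlinked(self):
        res = link([make_visit()], [])
        assert res.linked == () and len(res.unlinked_visits) == 1

    def test_one_link_per_category_fixture(self):
        """Six pairs, one constructed per category definition, all found."""
        specs = {  # category -> (H offset, S offset) minutes from arrival
            "L1": (0, 4000), "L2": (270, 4000), "L3": (100, 4000),
            "L4": (60, 180), "L5": (270 + 120, 4000), "L6": (-11, 1440),
        }
        visits, episodes = [], []
        for i, (cat, (h, s)) in enumerate(sorted(specs.items())):
            pid = f"P{i}"
            base = 10_000 * i
            visits.append(replace(make_visit(pid=pid, vid=f"V_{cat}"),
                                  arrival_dt=ts(base), departure_dt=ts(base + 270)))
            episodes.append(replace(make_episode(pid=pid, eid=f"E_{cat}"),
                                    admission_dt=ts(base + h),
                                    separation_dt=ts(base + s)))
        res = link(visits, episodes)
        assert {p.visit.visit_id: p.category for p in res.linked} == {
            f"V_{c}": c for c in specs}

    def test_partition_conservation_on_random_cohort(self):
        visits, episodes, _ = generate(SimConfig(n_participants=60, seed=7))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        res = link(visits, episodes)
        assert res.n_visits == len(visits)
        assert res.n_episodes == len(episodes)
        n_eligible = len(episodes) - len(res.continuation_episodes)
        assert len(res.linked) + len(res.unlinked_episodes) == n_eligible
        linked_v = [p.visit.visit_id for p in res.linked]
        linked_e = [p.episode.episode_id for p in res.linked]
        assert len(set(linked_v)) == len(linked_v)
        assert len(set(linked_e)) == len(linked_e)

    def test_chaining_off_exposes_continuations_as_targets(self):
        visits, episodes, _ = generate(SimConfig(n_participants=60, seed=7))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        flat = link(visits, episodes,
                    LinkWindowConfig(link_after_chaining=False))
        assert flat.continuation_episodes == ()
        assert len(flat.linked) + len(flat.unlinked_episodes) == len(episodes)

    def test_rerun_is_byte_identical(self):
        visits, episodes, _ = generate(SimConfig(n_participants=40, seed=3))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        assert link(visits, episodes).to_json() == link(visits, episodes).to_json()
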