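"""Cross-tabs, summary proportions, rounding and window sensitivity."""

from dataclasses import replace
from datetime import datetime, timedelta

import pytest

from tempolink.cleaning import validate_and_clean
from tempolink.codes import CodeMaps
from tempolink.linkage import LinkWindowConfig, link
from tempolink.metrics import (CrossTab2x2, admission_type_crosstab,
                               departure_status_crosstab, format_pct,
                               pct_half_up, summarize, summarize_counts,
                               window_sensitivity)
from tempolink.simulate import SimConfig, generate

from conftest import make_episode, make_visit


class TestRounding:
    @pytest.mark.parametrize("num, den, want", [
        (813, 1190, 68), (2210, 2269, 97), (1096, 1174, 93),
        (1190, 3459, 34), (1190, 1877, 63), (1, 200, 1), (1, 2, 50),
        (3, 200, 2),  # 1.5% rounds half-up to 2
    ])
    def test_half_up_integer_percent(self, num, den, want):
        assert pct_half_up(num, den) == want

    def test_degenerate_denominator(self):
        assert pct_half_up(0, 0) is None
        assert format_pct(0, 0) == "n/a"

    def test_small_nonzero_share_renders_below_one_percent(self):
        assert format_pct(1, 300, ) == "<1%"
        assert format_pct(7, 1190) == "1%"
        assert format_pct(0, 1190) == "0%"


class TestSummarize:
    def test_cohort_scale_worked_example(self):
        s = summarize_counts(3459, 1877, 1190)
        assert s.pct_visits_linked == 34
        assert s.pct_episodes_linked == 63
        assert s.n_complete_dataset == 4146

    def test_category_histogram_percentages(self):
        hist = {"L1": 206, "L2": 7, "L3": 801, "L4": 21, "L5": 43, "L6": 112}
        s = summarize_counts(3459, 1877, 1190, hist)
        assert s.category_pct == {"L1": "17%", "L2": "1%", "L3": "67%",
                                  "L4": "2%", "L5": "4%", "L6": "9%"}

    def test_zero_links(self):
        s = summarize_counts(10, 5, 0)
        assert s.pct_visits_linked == 0
        assert s.n_complete_dataset == 15

    def test_histogram_must_sum_to_links(self):
        with pytest.raises(ValueError):
            summarize_counts(10, 5, 3, {"L1": 1})

    def test_summarize_result_reconciles_with_partition(self):
        visits, episodes, _ = generate(SimConfig(n_participants=50, seed=11))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        res = link(visits, episodes)
        s = summarize(res)
        assert s.n_visits == len(visits) and s.n_episodes == len(episodes)
        assert sum(s.category_histogram.values()) == s.n_linked
        assert s.n_complete_dataset == s.n_visits + s.n_episodes - s.n_linked


def _result_with_codes(n_linked_expected, n_linked_not, n_unlinked_expected,
                       n_unlinked_not):
    """Small cohort realising given departure-status crosstab cells."""
    visits, episodes = [], []
    i = 0
    for status, admitted, n in [
        ("ward_this_hospital", True, n_linked_expected),
        ("usual_residence", True, n_linked_not),
        ("ward_this_hospital", False, n_unlinked_expected),
        ("usual_residence", False, n_unlinked_not),
    ]:
        for _ in range(n):
            i += 1
            pid = f"P{i}"
            visits.append(make_visit(pid=pid, vid=f"V{i}", status=status))
            if admitted:
                episodes.append(make_episode(pid=pid, eid=f"E{i}"))
    return link(visits, episodes)


class TestCrossTabs:
    def test_departure_status_agreement_small(self):
        res = _result_with_codes(8, 2, 1, 9)
        tab, props = departure_status_crosstab(res)
        assert (tab.a, tab.b, tab.c, tab.d) == (8, 1, 2, 9)
        assert props["linked_agreement_pct"] == 80
        assert props["unlinked_agreement_pct"] == 90

    def test_all_linked_admission_expected(self):
        res = _result_with_codes(10, 0, 0, 0)
        _, props = departure_status_crosstab(res)
        assert props["linked_agreement_pct"] == 100

    def test_degenerate_empty_input(self):
        res = _result_with_codes(0, 0, 0, 0)
        tab, props = departure_status_crosstab(res)
        assert tab.total == 0
        assert props["linked_agreement_pct"] is None

    def test_unmapped_codes_excluded_and_itemised(self):
        res = _result_with_codes(2, 0, 0, 2)
        odd = replace(res.unlinked_visits[0], departure_status="code_99")
        res = replace(res, unlinked_visits=(odd,) + res.unlinked_visits[1:])
        tab, _ = departure_status_crosstab(res)
        assert tab.excluded_unmapped == (odd.visit_id,)
        assert tab.total == 3

    def test_admission_type_found_link_rate(self):
        # 3 of 4 ED-expected episodes linked -> 75%
        visits = [make_visit(pid=f"P{i}", vid=f"V{i}") for i in range(3)]
        episodes = [make_episode(pid=f"P{i}", eid=f"E{i}") for i in range(3)]
        episodes.append(make_episode(pid="P9", eid="E9"))  # unlinked, ED-expected
        res = link(visits, episodes)
        tab, props = admission_type_crosstab(res)
        assert (tab.a, tab.b) == (3, 1)
        assert props["found_link_rate_ed_expected_pct"] == 75

    def test_no_ed_expected_episodes_rate_unavailable(self):
        e = make_episode(atype="waiting_list")
        res = link([], [e])
        _, props = admission_type_crosstab(res)
        assert props["found_link_rate_ed_expected_pct"] is None

    def test_margins_reconcile_with_partition(self):
        visits, episodes, _ = generate(SimConfig(n_participants=50, seed=13))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        res = link(visits, episodes)
        ds, _ = departure_status_crosstab(res)
        assert ds.total + len(ds.excluded_unmapped) == res.n_visits
        assert ds.col_totals[0] <= len(res.linked)
        at, _ = admission_type_crosstab(res)
        assert at.total + len(at.excluded_unmapped) == res.n_episodes
        assert at.col_totals[0] == len(res.linked)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            CrossTab2x2(1, -1, 0, 0)


class TestWindowSensitivity:
    def _l5_fixture(self, lags_min):
        visits, episodes = [], []
        for i, lag in enumerate(lags_min):
            pid = f"P{i}"
            v = make_visit(pid=pid, vid=f"V{i}",
                           arrival="2010-03-01 10:00", los_min=120)
            episodes.append(replace(
                make_episode(pid=pid, eid=f"E{i}"),
                admission_dt=v.departure_dt + timedelta(minutes=lag),
                separation_dt=v.departure_dt + timedelta(minutes=lag + 2880)))
            visits.append(v)
        return visits, episodes

    def test_window_forces_l5_link_in_or_out(self):
        visits, episodes = self._l5_fixture([120])  # H - D = 2 h
        rows = window_sensitivity(visits, episodes,
                                  [timedelta(0), timedelta(hours=24)])
        assert [r["n_linked"] for r in rows] == [0, 1]

    def test_default_window_matches_link_output(self):
        visits, episodes, _ = generate(SimConfig(n_participants=40, seed=5))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        (row,) = window_sensitivity(visits, episodes, [timedelta(hours=24)])
        res = link(visits, episodes)
        assert row["n_linked"] == len(res.linked)
        counts = res.summary_counts()
        assert all(row[f"n_{c}"] == counts[f"n_{c}"]
                   for c in ("L1", "L2", "L3", "L4", "L5", "L6"))

    def test_candidate_counts_follow_planted_lags(self):
        # lags 30 min, 90 min, 20 h against windows 1 h, 2 h, 24 h
        visits, episodes = self._l5_fixture([30, 90, 1200])
        rows = window_sensitivity(
            visits, episodes,
            [timedelta(hours=1), timedelta(hours=2), timedelta(hours=24)])
        assert [r["n_candidates"] for r in rows] == [1, 2, 3]

    def test_candidate_monotonicity_on_random_cohort(self):
        visits, episodes, _ = generate(SimConfig(n_participants=40, seed=9))
        visits, _ = validate_and_clean(visits)
        episodes, _ = validate_and_clean(episodes)
        rows = window_sensitivity(
            visits, episodes,
            [timedelta(hours=h) for h in (0, 1, 2, 6, 12, 24, 48)])
        cands = [r["n_candidates"] for r in rows]
        assert cands == sorted(cands)
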