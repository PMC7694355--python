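"""Synthetic frequent-presenter cohort with planted linkage ground truth.

Real ED-visit and admitted-episode extracts for the study population are
protected, so this module generates de-identified tables with the same
shape and the statistical features that make frequent-presenter linkage
hard: heavy-tailed per-person visit counts, multiple same-day
presentations, admission timestamps planted to satisfy each of the six
temporal link categories, planned-transfer chains of up to five
episodes, disposition-code misclassification, direct admissions with no
ED visit, and midnight date-entry slips.

The generator is *inverse* to the linkage rules: for every admitted
visit it draws a link category and constructs admission/separation
timestamps satisfying exactly that category's definition.  Encounters
for one person are placed in well-separated time slots so that, before
error injection, the planted pairing is the unique classifiable one —
running the linkage engine on clean output must recover the ground
truth exactly.  Injected errors are recorded so recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .codes import CodeMaps
from .cohort import IdentifierRecord
from .records import EDVisit, HospitalEpisode

#: per-category link counts of the reference frequent-presenter cohort
REFERENCE_CATEGORY_COUNTS = {"L1": 206, "L2": 7, "L3": 801, "L4": 21, "L5": 43, "L6": 112}
#: total-hospital-stay chain-length counts of the reference cohort
REFERENCE_CHAIN_COUNTS = {1: 1654, 2: 94, 3: 6, 4: 3, 5: 1}

_SLOT_DAYS = 21  # inter-encounter spacing; > 24 h windows + max stay span
_MINUTES_PER_DAY = 1440


def _normalized(d: dict, keys) -> dict:
    total = float(sum(d.get(k, 0.0) for k in keys))
    if total <= 0:
        raise ValueError("probability vector must have positive mass")
    return {k: float(d.get(k, 0.0)) / total for k in keys}


class SimConfig(BaseModel):
    """Stated world of the synthetic cohort.

    Defaults reproduce the reference cohort's scale: 688 participants
    observed January 2008 – June 2013, ~5 visits per participant on
    average (heavy-tailed), 34% of visits admitted, the printed link-
    category mix and transfer-chain-length distribution, 568 direct
    admissions with no ED visit, asymmetric disposition-code
    misclassification rates, and rare midnight date-entry errors.
    """

    n_participants: int = 688
    study_start: date = date(2008, 1, 1)
    study_end: date = date(2013, 6, 30)
    visit_rate_mean: float = 5.03
    visit_rate_dispersion: float = 0.8  # negative-binomial size; small = heavy tail
    p_admission_given_visit: float = 1190 / 3459
    category_mix: dict[str, float] = Field(
        default_factory=lambda: dict(REFERENCE_CATEGORY_COUNTS),
        validate_default=True,
    )
    chain_length_distribution: dict[int, float] = Field(
        default_factory=lambda: dict(REFERENCE_CHAIN_COUNTS),
        validate_default=True,
    )
    # (p flip when admission truly occurred, p flip when it did not)
    p_departure_status_misclassified: tuple[float, float] = (377 / 1190, 59 / 2269)
    # (p flip on linked index episodes, p flip on unlinked episodes)
    p_admission_type_uncertain: tuple[float, float] = (94 / 1190, 79 / 687)
    p_midnight_error: float = 0.004
    l5_within_2h_mass: float = 0.7
    l6_within_11min_mass: float = 0.9
    n_direct_admissions: int = 568
    p_same_day_repeat: float = 0.15
    ed_los_median_min: float = 180.0
    ed_los_sigma: float = 0.5
    hospital_los_median_min: float = 2880.0
    hospital_los_sigma: float = 0.8
    seed: int = 0

    model_config = {"frozen": True}

    @field_validator("category_mix")
    @classmethod
    def _norm_mix(cls, v):
        return _normalized(v, ("L1", "L2", "L3", "L4", "L5", "L6"))

    @field_validator("chain_length_distribution")
    @classmethod
    def _norm_chain(cls, v):
        v = {int(k): float(p) for k, p in v.items()}
        if any(k < 1 or k > 5 for k in v):
            raise ValueError("chain lengths must be in 1..5")
        return _normalized(v, (1, 2, 3, 4, 5))

    def model_post_init(self, __context) -> None:
        if self.study_end <= self.study_start:
            raise ValueError("study_end must be after study_start")
        for name in ("p_admission_given_visit", "p_midnight_error",
                     "l5_within_2h_mass", "l6_within_11min_mass",
                     "p_same_day_repeat"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass
class GroundTruth:
    """Planted structure of one generated cohort."""

    true_links: set[tuple[str, str, str]] = field(default_factory=set)  # (visit, episode, category)
    true_chains: dict[str, tuple[int, int]] = field(default_factory=dict)  # episode -> (chain id, position)
    injected_errors: list[tuple[str, str]] = field(default_factory=list)  # (record id, kind)
    visit_ids: set[str] = field(default_factory=set)
    episode_ids: set[str] = field(default_factory=set)

    @property
    def true_link_pairs(self) -> set[tuple[str, str]]:
        return {(v, e) for v, e, _ in self.true_links}

    def true_label(self, episode_id: str) -> str:
        return "index" if self.true_chains[episode_id][1] == 0 else "continuation"


def _lognormal_minutes(rng, median: float, sigma: float, lo: int, hi: int) -> int:
    x = math.exp(rng.normal(math.log(median), sigma))
    return int(min(max(x, lo), hi))


def _choice(rng, items: Sequence[str], weights: Sequence[float]) -> str:
    return items[int(rng.choice(len(items), p=np.asarray(weights) / sum(weights)))]


class _IdFactory:
    def __init__(self) -> None:
        self.v = 0
        self.e = 0

    def visit(self) -> str:
        self.v += 1
        return f"V{self.v:06d}"

    def episode(self) -> str:
        self.e += 1
        return f"E{self.e:06d}"


def _plant_quadruple(rng, cfg: SimConfig, arrival: datetime, ed_los: int,
                     category: str) -> tuple[datetime, datetime]:
    """Admission/separation timestamps satisfying ``category`` exactly
    for a visit spanning ``[arrival, arrival + ed_los]`` minutes."""
    departure = arrival + timedelta(minutes=ed_los)
    hosp_los = _lognormal_minutes(
        rng, cfg.hospital_los_median_min, cfg.hospital_los_sigma, 60, 4 * _MINUTES_PER_DAY
    )
    if category == "L1":
        h = arrival
        s = h + timedelta(minutes=hosp_los)
    elif category == "L2":
        h = departure
        s = h + timedelta(minutes=hosp_los)
    elif category == "L3":
        h = arrival + timedelta(minutes=int(rng.integers(1, ed_los)))
        s = departure + timedelta(minutes=hosp_los)
    elif category == "L4":
        h_off = int(rng.integers(1, ed_los - 1))
        s_off = int(rng.integers(h_off, ed_los))
        h = arrival + timedelta(minutes=h_off)
        s = arrival + timedelta(minutes=s_off)
    elif category == "L5":
        if rng.random() < cfg.l5_within_2h_mass:
            gap = int(rng.integers(1, 121))
        else:
            gap = int(rng.integers(121, _MINUTES_PER_DAY + 1))
        h = departure + timedelta(minutes=gap)
        s = h + timedelta(minutes=hosp_los)
    elif category == "L6":
        if rng.random() < cfg.l6_within_11min_mass:
            offset = int(rng.integers(1, 12))
        else:
            offset = int(rng.integers(12, _MINUTES_PER_DAY + 1))
        h = arrival - timedelta(minutes=offset)
        s = arrival + timedelta(minutes=hosp_los)  # arrival strictly before separation
    else:
        raise ValueError(f"unknown category {category!r}")
    return h, s


def _departure_status(rng, cfg: SimConfig, admitted: bool,
                      errors: list, visit_id: str) -> str:
    expected = _choice(
        rng,
        ["ward_this_hospital", "procedure_room_this_campus", "transfer_other_campus"],
        [0.90, 0.05, 0.05],
    )
    not_expected = _choice(
        rng,
        ["usual_residence", "left_before_completion", "died_in_ed"],
        [0.84, 0.15, 0.01],
    )
    p_flip = cfg.p_departure_status_misclassified[0 if admitted else 1]
    if rng.random() < p_flip:
        errors.append((visit_id, "departure_status_misclassified"))
        return not_expected if admitted else expected
    return expected if admitted else not_expected


def _admission_type(rng, cfg: SimConfig, linked_index: bool, continuation: bool,
                    errors: list, episode_id: str) -> str:
    uncertain = (
        "statistical_admission" if continuation else _choice(
            rng,
            ["waiting_list", "other_admission", "maternity", "other_emergency"],
            [0.35, 0.35, 0.05, 0.25],
        )
    )
    p_flip = cfg.p_admission_type_uncertain[0 if linked_index else 1]
    if rng.random() < p_flip:
        errors.append((episode_id, "admission_type_misclassified"))
        return uncertain if linked_index else "emergency_this_hospital"
    return "emergency_this_hospital" if linked_index else uncertain


def _build_chain(rng, cfg: SimConfig, ids: _IdFactory, pid: str,
                 index_admission: datetime, index_separation: datetime,
                 chain_len: int, linked_index: bool,
                 truth: GroundTruth, chain_id: int,
                 errors: list) -> list[HospitalEpisode]:
    """Materialise one total hospital stay of ``chain_len`` episodes."""
    episodes: list[HospitalEpisode] = []
    adm, sep = index_admission, index_separation
    for pos in range(chain_len):
        eid = ids.episode()
        is_last = pos == chain_len - 1
        if is_last:
            mode = _choice(rng, ["home", "died_in_hospital", "left_own_risk"],
                           [0.92, 0.03, 0.05])
        else:
            mode = _choice(rng, ["statistical_separation", "transfer_other_hospital"],
                           [0.7, 0.3])
        atype = _admission_type(rng, cfg, linked_index and pos == 0, pos > 0,
                                errors, eid)
        episodes.append(HospitalEpisode(
            participant_id=pid,
            episode_id=eid,
            admission_dt=adm,
            separation_dt=sep,
            admission_type=atype,
            separation_mode=mode,
            campus=f"C{int(rng.integers(1, 6))}",
            care_type="acute" if pos == 0 else _choice(
                rng, ["acute", "rehabilitation", "geriatric"], [0.3, 0.5, 0.2]),
        ))
        truth.true_chains[eid] = (chain_id, pos)
        truth.episode_ids.add(eid)
        if not is_last:
            gap = int(rng.integers(0, 1381))  # within the 24-h chain window
            adm = sep + timedelta(minutes=gap)
            cont_los = _lognormal_minutes(
                rng, cfg.hospital_los_median_min, cfg.hospital_los_sigma,
                60, 2 * _MINUTES_PER_DAY)
            sep = adm + timedelta(minutes=cont_los)
    return episodes


def _inject_midnight_errors(rng, cfg: SimConfig, visits, episodes, truth):
    """Shift an end date back one day on eligible short records, creating
    the end-before-start signature that cleaning repairs."""
    out_v: list[EDVisit] = []
    for v in visits:
        dur = v.departure_dt - v.arrival_dt
        if timedelta(0) < dur <= timedelta(hours=24) and rng.random() < cfg.p_midnight_error:
            out_v.append(EDVisit(**{
                **v.__dict__, "flags": (),
                "departure_dt": v.departure_dt - timedelta(days=1)}))
            truth.injected_errors.append((v.visit_id, "midnight_date_slip"))
        else:
            out_v.append(v)
    out_e: list[HospitalEpisode] = []
    for e in episodes:
        dur = e.separation_dt - e.admission_dt
        if timedelta(0) < dur <= timedelta(hours=24) and rng.random() < cfg.p_midnight_error:
            out_e.append(HospitalEpisode(**{
                **e.__dict__, "flags": (),
                "separation_dt": e.separation_dt - timedelta(days=1)}))
            truth.injected_errors.append((e.episode_id, "midnight_date_slip"))
        else:
            out_e.append(e)
    return out_v, out_e


def generate(config: SimConfig | None = None
             ) -> tuple[list[EDVisit], list[HospitalEpisode], GroundTruth]:
    """Generate a synthetic cohort; seeded and reproducible.

    Per participant, encounter *events* (an admitted visit with its
    episode chain, a cluster of same-day non-admitted visits, or a
    direct admission) are assigned to distinct 21-day slots across the
    study window, which guarantees no cross-event candidate pair is
    classifiable and the planted links are uniquely recoverable.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    ids = _IdFactory()
    truth = GroundTruth()
    visits: list[EDVisit] = []
    episodes: list[HospitalEpisode] = []

    total_days = (cfg.study_end - cfg.study_start).days
    n_slots = total_days // _SLOT_DAYS
    study_start = datetime.combine(cfg.study_start, datetime.min.time())

    k = cfg.visit_rate_dispersion
    p_nb = k / (k + cfg.visit_rate_mean)
    n_visits_per = rng.negative_binomial(k, p_nb, size=cfg.n_participants)
    direct_per = np.bincount(
        rng.integers(0, cfg.n_participants, size=cfg.n_direct_admissions),
        minlength=cfg.n_participants,
    )

    cats = sorted(cfg.category_mix)
    cat_p = np.array([cfg.category_mix[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    lens = sorted(cfg.chain_length_distribution)
    len_p = np.array([cfg.chain_length_distribution[l] for l in lens])
    len_p = len_p / len_p.sum()

    chain_id = 0
    for i in range(cfg.n_participants):
        pid = f"P{i + 1:04d}"
        n_visits = int(n_visits_per[i])
        n_direct = int(direct_per[i])
        admitted = rng.random(n_visits) < cfg.p_admission_given_visit
        n_adm = int(admitted.sum())
        n_unadm = n_visits - n_adm

        # group non-admitted visits into same-day clusters
        clusters: list[int] = []
        remaining = n_unadm
        while remaining > 0:
            size = 1
            while remaining - size > 0 and size < 3 and rng.random() < cfg.p_same_day_repeat:
                size += 1
            clusters.append(size)
            remaining -= size

        n_events = n_adm + n_direct + len(clusters)
        if n_events > n_slots:  # extremely heavy tail: shed non-admitted clusters first
            while len(clusters) > 0 and n_events > n_slots:
                n_unadm -= clusters.pop()
                n_events -= 1
            n_adm = min(n_adm, n_slots - n_direct - len(clusters))
            n_events = n_adm + n_direct + len(clusters)
        slots = rng.choice(n_slots, size=n_events, replace=False)

        event_kinds = (["adm"] * n_adm) + (["direct"] * n_direct) + (
            ["cluster"] * len(clusters)
        )
        cluster_iter = iter(clusters)
        for kind, slot in zip(event_kinds, slots):
            base = study_start + timedelta(
                days=int(slot) * _SLOT_DAYS,
                minutes=int(rng.integers(0, 2 * _MINUTES_PER_DAY)),
            )
            if kind == "adm":
                ed_los = _lognormal_minutes(rng, cfg.ed_los_median_min,
                                            cfg.ed_los_sigma, 30, 1380)
                vid = ids.visit()
                category = cats[int(rng.choice(len(cats), p=cat_p))]
                h, s = _plant_quadruple(rng, cfg, base, ed_los, category)
                chain_len = lens[int(rng.choice(len(lens), p=len_p))]
                chain = _build_chain(rng, cfg, ids, pid, h, s, chain_len,
                                     linked_index=True, truth=truth,
                                     chain_id=chain_id,
                                     errors=truth.injected_errors)
                chain_id += 1
                episodes.extend(chain)
                truth.true_links.add((vid, chain[0].episode_id, category))
                visits.append(EDVisit(
                    participant_id=pid,
                    visit_id=vid,
                    arrival_dt=base,
                    departure_dt=base + timedelta(minutes=ed_los),
                    departure_status=_departure_status(
                        rng, cfg, True, truth.injected_errors, vid),
                    campus=f"C{int(rng.integers(1, 6))}",
                    visit_type="emergency",
                ))
                truth.visit_ids.add(vid)
            elif kind == "direct":
                los = _lognormal_minutes(rng, cfg.hospital_los_median_min,
                                         cfg.hospital_los_sigma, 60,
                                         4 * _MINUTES_PER_DAY)
                chain_len = lens[int(rng.choice(len(lens), p=len_p))]
                chain = _build_chain(rng, cfg, ids, pid, base,
                                     base + timedelta(minutes=los), chain_len,
                                     linked_index=False, truth=truth,
                                     chain_id=chain_id,
                                     errors=truth.injected_errors)
                chain_id += 1
                episodes.extend(chain)
            else:  # cluster of same-day non-admitted visits
                arrival = base
                for _ in next(cluster_iter) * [None]:
                    ed_los = _lognormal_minutes(rng, cfg.ed_los_median_min,
                                                cfg.ed_los_sigma, 30, 300)
                    vid = ids.visit()
                    visits.append(EDVisit(
                        participant_id=pid,
                        visit_id=vid,
                        arrival_dt=arrival,
                        departure_dt=arrival + timedelta(minutes=ed_los),
                        departure_status=_departure_status(
                            rng, cfg, False, truth.injected_errors, vid),
                        campus=f"C{int(rng.integers(1, 6))}",
                        visit_type="emergency",
                    ))
                    truth.visit_ids.add(vid)
                    arrival = arrival + timedelta(
                        minutes=ed_los + int(rng.integers(10, 121)))

    visits, episodes = _inject_midnight_errors(rng, cfg, visits, episodes, truth)
    return visits, episodes, truth


# ---------------------------------------------------------------------------
# fixture builders used by tests and the acceptance checks

def planted_stay_population(
    chain_counts: dict[int, int] | None = None,
    seed: int = 0,
) -> list[HospitalEpisode]:
    """Episode table realising an exact chain-length census.

    Defaults to the reference cohort's printed distribution: 1654 single-
    episode stays plus 94 two-, 6 three-, 3 four- and 1 five-episode
    stays (1758 stays, 1877 episode records).  Every non-final episode
    carries a planned-transfer separation code and inter-episode gaps
    are under 24 h; distinct stays for one participant are separated by
    weeks so they can never merge.
    """
    counts = dict(chain_counts) if chain_counts is not None else dict(REFERENCE_CHAIN_COUNTS)
    rng = np.random.default_rng(seed)
    ids = _IdFactory()
    episodes: list[HospitalEpisode] = []
    base0 = datetime(2008, 1, 1, 8, 0)
    stays: list[int] = []
    for length in sorted(counts):
        stays.extend([length] * counts[length])
    # spread stays over participants, a few stays each
    for n, length in enumerate(stays):
        pid = f"S{n // 3 + 1:04d}"
        adm = base0 + timedelta(days=(n % 3) * 40, minutes=int(rng.integers(0, 1440)))
        for pos in range(length):
            sep = adm + timedelta(minutes=int(rng.integers(60, 2880)))
            last = pos == length - 1
            episodes.append(HospitalEpisode(
                participant_id=pid,
                episode_id=ids.episode(),
                admission_dt=adm,
                separation_dt=sep,
                admission_type="emergency_this_hospital" if pos == 0
                else "statistical_admission",
                separation_mode="home" if last else _choice(
                    rng, ["statistical_separation", "transfer_other_hospital"],
                    [0.7, 0.3]),
                care_type="acute" if pos == 0 else "rehabilitation",
            ))
            adm = sep + timedelta(minutes=int(rng.integers(0, 1381)))
    return episodes


def planted_category_pairs(
    category_counts: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[list[EDVisit], list[HospitalEpisode], GroundTruth]:
    """One (visit, episode) pair per requested link, each constructed to
    satisfy its category's temporal definition exactly.

    Defaults to the reference per-category link counts (1190 pairs).
    Each pair lives on its own participant, so classification of the
    planted quadruple is the only decision the engine has to make.
    """
    counts = dict(category_counts) if category_counts is not None else dict(REFERENCE_CATEGORY_COUNTS)
    cfg = SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    ids = _IdFactory()
    truth = GroundTruth()
    visits: list[EDVisit] = []
    episodes: list[HospitalEpisode] = []
    n = 0
    for category in sorted(counts):
        for _ in range(counts[category]):
            n += 1
            pid = f"Q{n:05d}"
            base = datetime(2010, 1, 1) + timedelta(
                days=int(rng.integers(0, 900)), minutes=int(rng.integers(0, 1440)))
            ed_los = _lognormal_minutes(rng, cfg.ed_los_median_min,
                                        cfg.ed_los_sigma, 30, 1380)
            h, s = _plant_quadruple(rng, cfg, base, ed_los, category)
            vid, eid = ids.visit(), ids.episode()
            visits.append(EDVisit(
                participant_id=pid, visit_id=vid,
                arrival_dt=base, departure_dt=base + timedelta(minutes=ed_los),
                departure_status="ward_this_hospital"))
            episodes.append(HospitalEpisode(
                participant_id=pid, episode_id=eid,
                admission_dt=h, separation_dt=s,
                admission_type="emergency_this_hospital", separation_mode="home"))
            truth.true_links.add((vid, eid, category))
            truth.visit_ids.add(vid)
            truth.episode_ids.add(eid)
            truth.true_chains[eid] = (n - 1, 0)
    return visits, episodes, truth


def generate_identifiers(
    n: int, seed: int = 0, participant_prefix: str = "P"
) -> list[IdentifierRecord]:
    """Synthetic Medicare-like identifier records (no real-world validity)."""
    rng = np.random.default_rng(seed)
    names = ["alex", "bree", "carl", "dana", "evan", "fern", "gwen", "hugo",
             "iris", "jude", "kira", "liam", "mona", "nils", "opal", "pria"]
    out = []
    for i in range(n):
        out.append(IdentifierRecord(
            record_id=f"{participant_prefix}{i + 1:04d}",
            medicare_number=f"{int(rng.integers(2, 7))}{int(rng.integers(0, 10**8)):08d}",
            first_name=str(rng.choice(names)),
            date_of_birth=(date(1955, 1, 1) + timedelta(
                days=int(rng.integers(0, 14000)))).isoformat(),
            sex=str(rng.choice(["f", "m"])),
        ))
    return out


# ---------------------------------------------------------------------------
# recovery scoring

@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    n_true: int
    n_found: int
    n_correct: int
    per_category_recall: dict[str, float]
    category_confusion: dict[tuple[str, str], int]  # (planted, found) -> count
    chain_label_accuracy: float | None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "n_true": self.n_true,
            "n_found": self.n_found,
            "n_correct": self.n_correct,
            "per_category_recall": self.per_category_recall,
            "category_confusion": {
                f"{a}->{b}": c for (a, b), c in sorted(self.category_confusion.items())
            },
            "chain_label_accuracy": self.chain_label_accuracy,
        }


def evaluate_recovery(result, chains, truth: GroundTruth) -> RecoveryMetrics:
    """Score a linkage run against the planted ground truth.

    ``result`` is a LinkageResult produced from the generated tables and
    ``chains`` the chaining output on the same episodes (may be None to
    skip chain scoring).  Raises if the result references identifiers
    the truth has never seen.
    """
    found = {(p.visit.visit_id, p.episode.episode_id): p.category
             for p in result.linked}
    unknown_v = {v for v, _ in found} - truth.visit_ids
    unknown_e = {e for _, e in found} - truth.episode_ids
    if unknown_v or unknown_e:
        raise ValueError(
            f"result references unknown ids: visits={sorted(unknown_v)[:3]} "
            f"episodes={sorted(unknown_e)[:3]}"
        )
    planted = {(v, e): c for v, e, c in truth.true_links}
    correct = set(found) & set(planted)
    precision = len(correct) / len(found) if found else 1.0
    recall = len(correct) / len(planted) if planted else 1.0

    per_cat: dict[str, float] = {}
    for cat in sorted({c for c in planted.values()}):
        cat_pairs = {k for k, c in planted.items() if c == cat}
        per_cat[cat] = (len(cat_pairs & set(found)) / len(cat_pairs)) if cat_pairs else 1.0

    confusion: dict[tuple[str, str], int] = {}
    for k in correct:
        key = (planted[k], found[k])
        confusion[key] = confusion.get(key, 0) + 1

    chain_acc = None
    if chains is not None and truth.true_chains:
        labels: dict[str, str] = {}
        for ch in chains:
            labels[ch.index_episode.episode_id] = "index"
            for cont in ch.continuations:
                labels[cont.episode_id] = "continuation"
        scored = [eid for eid in labels if eid in truth.true_chains]
        if scored:
            chain_acc = sum(
                1 for eid in scored if labels[eid] == truth.true_label(eid)
            ) / len(scored)
    return RecoveryMetrics(
        precision=precision, recall=recall,
        n_true=len(planted), n_found=len(found), n_correct=len(correct),
        per_category_recall=per_cat, category_confusion=confusion,
        chain_label_accuracy=chain_acc,
    )
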