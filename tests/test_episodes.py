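"""Adult filter, 48-hour episode merging and patient-day arithmetic."""

from __future__ import annotations

from datetime import timedelta

import networkx as nx
import numpy as np
import pytest

from icuamc.episodes import build_episodes, filter_adults, patient_days
from icuamc.issues import IssueLog
from tests.conftest import T0


def brute_force_partition(admissions, gap_threshold_hours=48.0):
    """Independent oracle: connected components of the pairwise-gap graph.

    Two admissions of one patient connect when the gap between the earlier
    discharge and the later admission is strictly below the threshold.
    """
    graph = nx.Graph()
    graph.add_nodes_from(a.admission_id for a in admissions)
    by_patient = {}
    for a in admissions:
        by_patient.setdefault(a.patient_id, []).append(a)
    for group in by_patient.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                first, second = (a, b) if a.admit_ts <= b.admit_ts else (b, a)
                gap = (second.admit_ts - first.discharge_ts).total_seconds() / 3600.0
                if gap < gap_threshold_hours:
                    graph.add_edge(a.admission_id, b.admission_id)
    return {frozenset(c) for c in nx.connected_components(graph)}


def random_admissions(rng, make_admission, n_patients=3, max_per_patient=50):
    """Non-overlapping per-patient admission chains with adversarial gaps."""
    admissions = []
    for p in range(n_patients):
        cursor = T0 + timedelta(hours=float(rng.uniform(0, 200)))
        for _ in range(int(rng.integers(1, max_per_patient + 1))):
            los_h = float(rng.uniform(3, 120))
            adm = make_admission(patient_id=f"P{p}", admit_ts=cursor,
                                 discharge_ts=cursor + timedelta(hours=los_h))
            admissions.append(adm)
            gap_h = float(rng.choice([rng.uniform(0.1, 47.9), 48.0,
                                      rng.uniform(48.1, 400)]))
            cursor = adm.discharge_ts + timedelta(hours=gap_h)
    return admissions


class TestFilterAdults:
    def test_boundary_at_18(self, make_admission):
        admissions = [make_admission(age_years=a) for a in (17, 18, 65)]
        kept, excluded = filter_adults(admissions)
        assert [a.age_years for a in kept] == [18, 65]
        assert excluded == 1

    def test_all_adults_none_excluded(self, make_admission):
        kept, excluded = filter_adults([make_admission() for _ in range(5)])
        assert len(kept) == 5 and excluded == 0

    def test_generated_minors_fraction(self, small_cohort):
        truth = small_cohort["truth"]
        n_minors = sum(1 for t in truth["admissions"].values() if t["age_years"] < 18)
        assert small_cohort["result"].minors_excluded == n_minors


class TestBuildEpisodes:
    def test_short_gap_merges(self, make_admission):
        a1 = make_admission(patient_id="P", admit_ts=T0,
                            discharge_ts=T0 + timedelta(hours=26))
        a2 = make_admission(patient_id="P", admit_ts=a1.discharge_ts + timedelta(hours=23),
                            discharge_ts=a1.discharge_ts + timedelta(hours=40))
        (episode,) = build_episodes([a1, a2])
        assert episode.admission_ids == (a1.admission_id, a2.admission_id)

    def test_exact_48h_gap_splits(self, make_admission):
        a1 = make_admission(patient_id="P", admit_ts=T0,
                            discharge_ts=T0 + timedelta(hours=26))
        a2 = make_admission(patient_id="P", admit_ts=a1.discharge_ts + timedelta(hours=48),
                            discharge_ts=a1.discharge_ts + timedelta(hours=80))
        episodes = build_episodes([a1, a2])
        assert len(episodes) == 2

    def test_gap_contributes_no_patient_days(self, make_admission):
        a1 = make_admission(patient_id="P", admit_ts=T0,
                            discharge_ts=T0 + timedelta(hours=24))
        a2 = make_admission(patient_id="P", admit_ts=T0 + timedelta(hours=40),
                            discharge_ts=T0 + timedelta(hours=52))
        (episode,) = build_episodes([a1, a2])
        assert episode.los_days == pytest.approx((24 + 12) / 24)

    def test_overlap_rejected(self, make_admission):
        a1 = make_admission(patient_id="P", admit_ts=T0,
                            discharge_ts=T0 + timedelta(hours=48))
        a2 = make_admission(patient_id="P", admit_ts=T0 + timedelta(hours=10),
                            discharge_ts=T0 + timedelta(hours=60))
        log = IssueLog()
        episodes = build_episodes([a1, a2], log=log)
        assert len(episodes) == 1
        assert [i.code for i in log.rejects] == ["overlapping_admission"]

    def test_outcome_propagation(self, make_admission):
        a1 = make_admission(patient_id="P", admit_ts=T0,
                            discharge_ts=T0 + timedelta(hours=26),
                            died_in_icu=True, died_within_30d=True)
        a2 = make_admission(patient_id="P", admit_ts=a1.discharge_ts + timedelta(hours=5),
                            discharge_ts=a1.discharge_ts + timedelta(hours=30),
                            died_in_icu=False, died_within_30d=False)
        (episode,) = build_episodes([a1, a2])
        assert episode.died_in_icu is True            # any member
        assert episode.died_within_30d is False       # last member

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_pairwise_gap_oracle(self, make_admission, seed):
        rng = np.random.default_rng(seed)
        admissions = random_admissions(rng, make_admission)
        episodes = build_episodes(admissions)
        got = {frozenset(e.admission_ids) for e in episodes}
        assert got == brute_force_partition(admissions)

    def test_partition_property(self, make_admission):
        rng = np.random.default_rng(99)
        admissions = random_admissions(rng, make_admission, n_patients=5)
        episodes = build_episodes(admissions)
        member_ids = [i for e in episodes for i in e.admission_ids]
        assert sorted(member_ids) == sorted(a.admission_id for a in admissions)

    def test_merge_idempotent(self, make_admission):
        rng = np.random.default_rng(7)
        admissions = random_admissions(rng, make_admission)
        first = build_episodes(admissions)
        flattened = [a for e in first for a in e.admissions]
        second = build_episodes(flattened)
        assert ({frozenset(e.admission_ids) for e in first}
                == {frozenset(e.admission_ids) for e in second})

    @pytest.mark.parametrize("seed", range(10))
    def test_threshold_monotonicity(self, make_admission, seed):
        """Raising the merge threshold never increases the episode count."""
        rng = np.random.default_rng(seed)
        admissions = random_admissions(rng, make_admission, n_patients=2,
                                       max_per_patient=8)
        counts = [len(build_episodes(admissions, gap_threshold_hours=h))
                  for h in (12.0, 48.0, 96.0, 1e6)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestPatientDays:
    def test_36_hour_stay(self, make_admission):
        adm = make_admission(discharge_ts=T0 + timedelta(hours=36))
        assert patient_days([adm]) == pytest.approx(1.5)

    def test_empty_set(self):
        assert patient_days([]) == 0.0

    def test_additive_over_disjoint_admissions(self, make_admission):
        a = make_admission(discharge_ts=T0 + timedelta(hours=10))
        b = make_admission(admit_ts=T0 + timedelta(days=5),
                           discharge_ts=T0 + timedelta(days=5, hours=30))
        assert patient_days([a, b]) == pytest.approx(patient_days([a]) + patient_days([b]))
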