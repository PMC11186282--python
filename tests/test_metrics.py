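"""DOT/LOT/DDD definitions, normalisation and conservation."""

from __future__ import annotations

from datetime import timedelta

import pytest

from icuamc.metrics import (
    StratumMetrics,
    admission_metrics,
    aggregate,
    ddd_administered,
    derived_ratios,
    dot,
    lot,
    rate_per_1000_pd,
    therapy_days,
)
from tests.conftest import T0


def brute_force_dot_lot(linked, registry):
    """Independent oracle: count distinct triples / pairs directly."""
    triples = set()
    for admission_id, doses in linked.items():
        for d in doses:
            if d.atc_code is not None and d.atc_code in registry:
                triples.add((admission_id, d.timestamp.date(), d.atc_code))
    pairs = {(a, day) for a, day, _ in triples}
    return len(triples), len(pairs)


class TestTherapyDays:
    def test_repeat_doses_one_agent_day(self, registry, make_admission, make_dose):
        adm = make_admission()
        doses = [make_dose(adm.admission_id, T0.replace(hour=8)),
                 make_dose(adm.admission_id, T0.replace(hour=20))]
        days = therapy_days({adm.admission_id: doses}, registry)
        assert len(days) == 1
        assert days[0].agents == frozenset({"J01DD04"})

    def test_midnight_boundary_two_days(self, registry, make_admission, make_dose):
        adm = make_admission()
        doses = [make_dose(adm.admission_id, T0.replace(hour=23, minute=50)),
                 make_dose(adm.admission_id, (T0 + timedelta(days=1)).replace(hour=0, minute=10))]
        days = therapy_days({adm.admission_id: doses}, registry)
        assert len(days) == 2

    def test_non_antimicrobials_ignored(self, registry, make_admission, make_dose):
        adm = make_admission()
        doses = [make_dose(adm.admission_id, T0, atc_code="N05BA01", amount=5, amount_unit="mg")]
        assert therapy_days({adm.admission_id: doses}, registry) == []

    def test_matches_enumeration_oracle(self, registry, small_cohort):
        linked = small_cohort["result"].linked
        days = small_cohort["result"].therapy_days
        exp_dot, exp_lot = brute_force_dot_lot(linked, registry)
        assert dot(days) == exp_dot
        assert lot(days) == exp_lot


class TestDotLot:
    def test_multi_agent_day_counts_per_agent(self, registry, make_admission, make_dose):
        adm = make_admission()
        doses = [make_dose(adm.admission_id, T0, atc_code="J01DD04"),
                 make_dose(adm.admission_id, T0.replace(hour=12), atc_code="J01XA01",
                           amount=1.0),
                 make_dose(adm.admission_id, T0 + timedelta(days=1), atc_code="J01DD04")]
        days = therapy_days({adm.admission_id: doses}, registry)
        assert dot(days) == 3
        assert lot(days) == 2

    def test_five_agents_single_day(self, registry, make_admission, make_dose):
        adm = make_admission()
        codes = ["J01DD04", "J01XA01", "J01DH02", "J02AC01", "J01MA02"]
        doses = [make_dose(adm.admission_id, T0.replace(hour=6 + i), atc_code=c)
                 for i, c in enumerate(codes)]
        days = therapy_days({adm.admission_id: doses}, registry)
        assert (dot(days), lot(days)) == (5, 1)

    def test_empty(self):
        assert dot([]) == 0 and lot([]) == 0

    def test_dose_splitting_invariance(self, registry, make_admission, make_dose):
        """Splitting a dose in two same-day halves changes neither DOT/LOT nor DDD."""
        adm = make_admission()
        whole = {adm.admission_id: [make_dose(adm.admission_id, T0, amount=4.0)]}
        split = {adm.admission_id: [make_dose(adm.admission_id, T0, amount=2.0),
                                    make_dose(adm.admission_id, T0.replace(hour=14), amount=2.0)]}
        days_whole = therapy_days(whole, registry)
        days_split = therapy_days(split, registry)
        assert dot(days_whole) == dot(days_split)
        assert lot(days_whole) == lot(days_split)
        assert ddd_administered(whole, registry)[0] == pytest.approx(
            ddd_administered(split, registry)[0])


class TestDddAdministered:
    def test_simple_sum(self, registry, make_admission, make_dose):
        adm = make_admission()
        linked = {adm.admission_id: [
            make_dose(adm.admission_id, T0, amount=2.0),
            make_dose(adm.admission_id, T0 + timedelta(days=1), amount=2.0),
        ]}
        total, share = ddd_administered(linked, registry)
        assert total == pytest.approx(2.0)  # 4 g over a 2 g DDD
        assert share == 0.0

    def test_undefined_ddd_regimen_fully_excluded(self, registry, make_admission, make_dose):
        adm = make_admission()
        linked = {adm.admission_id: [
            make_dose(adm.admission_id, T0, atc_code="J01EE01", amount=0.8),
        ]}
        total, share = ddd_administered(linked, registry)
        assert total == 0.0
        assert share == 1.0

    def test_mixed_regimen_share(self, registry, make_admission, make_dose):
        adm = make_admission()
        linked = {adm.admission_id: [
            make_dose(adm.admission_id, T0, atc_code="J01DD04", amount=2.0),
            make_dose(adm.admission_id, T0.replace(hour=12), atc_code="J01XB01",
                      amount=3.0, amount_unit="MU"),
        ]}
        total, share = ddd_administered(linked, registry)
        assert total == pytest.approx(1.0)
        assert share == pytest.approx(0.5)  # colistin agent-day unconvertible


class TestRates:
    @pytest.mark.parametrize("total,days,expected", [
        (14466, 11469, pytest.approx(1261.3, abs=0.05)),
        (8322, 7068, pytest.approx(1177.4, abs=0.05)),
        (0, 5, 0.0),
    ])
    def test_rate_values(self, total, days, expected):
        assert rate_per_1000_pd(total, days) == expected

    def test_zero_denominator_undefined(self):
        assert rate_per_1000_pd(10, 0) is None

    def test_scale_consistency(self):
        assert rate_per_1000_pd(20, 16) == pytest.approx(rate_per_1000_pd(40, 32))


class TestDerivedRatios:
    def test_direct_division(self):
        stratum = StratumMetrics(key={}, dot=15, lot=10, ddd_administered=0.0,
                                 patient_days=10.0, n_admissions=5, n_amu_admissions=3)
        ratios = derived_ratios(stratum)
        assert ratios["lot_per_admission"] == pytest.approx(2.0)
        assert ratios["lot_per_amu_admission"] == pytest.approx(10 / 3)
        assert ratios["dot_lot_ratio"] == pytest.approx(1.5)

    def test_all_zero_stratum_has_absent_ratios(self):
        stratum = StratumMetrics(key={}, dot=0, lot=0, ddd_administered=0.0,
                                 patient_days=0.0, n_admissions=0, n_amu_admissions=0)
        assert derived_ratios(stratum) == {"lot_per_admission": None,
                                           "lot_per_amu_admission": None,
                                           "dot_lot_ratio": None}

    def test_dot_below_lot_is_invalid(self):
        with pytest.raises(ValueError):
            StratumMetrics(key={}, dot=1, lot=2, ddd_administered=0.0,
                           patient_days=1.0, n_admissions=1, n_amu_admissions=1)


class TestConservation:
    @pytest.mark.parametrize("partition", [["care_level"], ["referring_clinic"],
                                           ["sex"], ["age_band"], ["year"]])
    def test_stratified_totals_sum_to_grand_total(self, small_cohort, partition):
        frame = small_cohort["result"].adm_frame
        table = aggregate(frame, partition)
        for column in ("dot", "lot", "ddd_administered", "patient_days", "n_admissions"):
            assert table[column].sum() == pytest.approx(
                frame[column].sum() if column != "n_admissions" else len(frame))

    def test_class_dot_partitions_total(self, small_cohort):
        class_frame = small_cohort["result"].class_frame
        frame = small_cohort["result"].adm_frame
        assert class_frame["dot"].sum() == frame["dot"].sum()

    def test_admission_metrics_match_truth(self, small_cohort):
        frame = small_cohort["result"].adm_frame.set_index("admission_id")
        truth = small_cohort["truth"]["admissions"]
        for admission_id, row in frame.iterrows():
            expected = truth[admission_id]
            assert row["dot"] == expected["dot"]
            assert row["lot"] == expected["lot"]
            assert row["ddd_administered"] == pytest.approx(expected["ddd"], abs=1e-5)


def test_aggregate_empty_frame(small_cohort):
    frame = small_cohort["result"].adm_frame.iloc[0:0]
    table = aggregate(frame, ["care_level"])
    assert table.empty and "dot_rate" in table.columns


def test_admission_metrics_has_one_row_per_admission(small_cohort):
    result = small_cohort["result"]
    assert len(result.adm_frame) == len(result.admissions)
    rebuilt = admission_metrics(result.admissions, result.therapy_days,
                                result.linked, result.registry)
    assert rebuilt["dot"].sum() == result.adm_frame["dot"].sum()
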