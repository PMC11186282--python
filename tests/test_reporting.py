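"""Report tables, rounding, bootstrap CIs and deterministic rendering."""

from __future__ import annotations

import itertools
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from icuamc.episodes import build_episodes
from icuamc.reporting import (
    clinic_consumption,
    metric_comparison,
    percent,
    per_mille,
    population_table,
    render,
    round_half_up,
)
from icuamc.ingest import DispensingRecord
from tests.conftest import T0


class TestRounding:
    @pytest.mark.parametrize("value,ndigits,expected", [
        (1261.3, 0, 1261), (1177.4, 0, 1177), (0.5, 0, 1), (1.5, 0, 2),
        (2.5, 0, 3), (41.25, 1, 41.3), (41.24, 1, 41.2),
    ])
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected

    def test_percent_and_per_mille(self):
        assert percent(2315, 5608, 1) == 41.3
        assert per_mille(132, 22788) == 6
        assert percent(1, 0) is None


class TestPopulationTable:
    def test_female_percentage(self, make_admission):
        admissions = ([make_admission(sex="female") for _ in range(413)]
                      + [make_admission(sex="male") for _ in range(587)])
        table = population_table(build_episodes(admissions)).set_index("characteristic")
        assert table.loc["female_n_pct", "all"] == "413 (41.3)"

    def test_single_episode_degenerate_medians(self, make_admission):
        adm = make_admission(age_years=70, discharge_ts=T0 + timedelta(hours=36))
        table = population_table(build_episodes([adm])).set_index("characteristic")
        assert table.loc["median_age_iqr_yr", "all"] == "70 (70-70)"
        assert table.loc["median_los_iqr_days", "all"] == "1.5 (1.5-1.5)"

    def test_medians_match_sort_oracle(self, small_cohort):
        table = population_table(small_cohort["result"].episodes).set_index("characteristic")
        ages = [a.age_years for a in small_cohort["result"].admissions]
        q25, med, q75 = np.percentile(ages, [25, 50, 75])
        assert table.loc["median_age_iqr_yr", "all"] == f"{med:.0f} ({q25:.0f}-{q75:.0f})"

    def test_patient_days_match_metrics(self, small_cohort):
        table = population_table(small_cohort["result"].episodes).set_index("characteristic")
        expected = round_half_up(small_cohort["result"].adm_frame["patient_days"].sum())
        assert table.loc["patient_days_n", "all"] == str(expected)


class TestClinicConsumption:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["admission_id", "care_level",
                                           "referring_clinic", "dot", "patient_days"])

    def test_identical_admissions_zero_width_ci(self):
        frame = self._frame([(f"A{i}", "tertiary", "general_surgery", 4, 2.0)
                             for i in range(20)])
        table = clinic_consumption(frame, n_boot=200, seed=0)
        assert table["ci_low"].iloc[0] == table["ci_high"].iloc[0] == table["dot_rate"].iloc[0]

    def test_rates_consistent_with_totals(self, small_cohort):
        frame = small_cohort["result"].adm_frame
        table = clinic_consumption(frame, n_boot=50, seed=0)
        for row in table.itertuples():
            if row.dot_rate is None:
                continue
            members = frame[(frame["care_level"] == row.care_level)
                            & (frame["referring_clinic"] == row.referring_clinic)]
            expected = members["dot"].sum() / members["patient_days"].sum() * 1000
            assert row.dot_rate == round_half_up(expected)

    def test_bootstrap_ci_close_to_exhaustive_enumeration(self):
        """On a 5-admission toy, the resample distribution is enumerable."""
        dots = np.array([0, 2, 4, 6, 10], dtype=float)
        pdays = np.array([1.0, 2.0, 1.5, 3.0, 2.5])
        frame = self._frame([(f"A{i}", "tertiary", "general_surgery", d, p)
                             for i, (d, p) in enumerate(zip(dots, pdays))])
        exhaustive = []
        for idx in itertools.product(range(5), repeat=5):
            idx = list(idx)
            exhaustive.append(dots[idx].sum() / pdays[idx].sum() * 1000)
        lo, hi = np.percentile(exhaustive, [2.5, 97.5])
        table = clinic_consumption(frame, n_boot=4000, seed=3)
        assert table["ci_low"].iloc[0] == pytest.approx(lo, rel=0.08)
        assert table["ci_high"].iloc[0] == pytest.approx(hi, rel=0.08)

    def test_seeded_bootstrap_is_deterministic(self, small_cohort):
        frame = small_cohort["result"].adm_frame
        a = clinic_consumption(frame, n_boot=100, seed=42)
        b = clinic_consumption(frame, n_boot=100, seed=42)
        pd.testing.assert_frame_equal(a, b)


class TestMetricComparison:
    def _class_frame(self, registry):
        return pd.DataFrame([
            {"care_level": "tertiary", "class_label": "cephalosporin_3rd_gen",
             "atc_code": "J01DD04", "substance_name": "ceftriaxone",
             "dot": 100, "ddd_administered": 100.0},
        ])

    def test_dispensed_never_administered_flagged(self, registry):
        dispensing = [DispensingRecord("ALL", T0.date(), T0.date(), "J01CF02", 4000.0, "g")]
        table = metric_comparison(self._class_frame(registry), dispensing, registry,
                                  patient_days=1000.0)
        row = table[table["atc_code"] == "J01CF02"].iloc[0]
        assert row["dot"] == 0 and bool(row["divergence_flag"])

    def test_identical_totals_not_flagged(self, registry):
        dispensing = [DispensingRecord("ALL", T0.date(), T0.date(), "J01DD04", 200.0, "g")]
        table = metric_comparison(self._class_frame(registry), dispensing, registry,
                                  patient_days=1000.0)
        row = table[table["atc_code"] == "J01DD04"].iloc[0]
        assert row["dispensed_administered_ratio"] == pytest.approx(1.0)
        assert not bool(row["divergence_flag"])

    def test_rates_hand_computed(self, registry):
        dispensing = [DispensingRecord("ALL", T0.date(), T0.date(), "J01DD04", 500.0, "g")]
        table = metric_comparison(self._class_frame(registry), dispensing, registry,
                                  patient_days=1000.0, minors_count=10,
                                  minors_patient_days=250.0)
        row = table.iloc[0]
        assert row["dot_rate"] == 100                       # 100/1000*1000
        assert row["ddd_administered_rate"] == 100
        assert row["ddd_dispensed_rate"] == 200             # 250 DDD / 1250 pd
        assert row["minors_admissions_accounted"] == 10

    def test_without_dispensing_column_absent(self, registry):
        table = metric_comparison(self._class_frame(registry), [], registry,
                                  patient_days=1000.0)
        assert table["ddd_dispensed_rate"].isna().all()


class TestRender:
    def test_byte_identical_re_render(self, small_cohort, tmp_path):
        bundle = small_cohort["result"].report_bundle(n_boot=50, seed=5)
        paths_a = render(bundle, tmp_path / "a", provenance="config_sha256=deadbeef")
        paths_b = render(bundle, tmp_path / "b", provenance="config_sha256=deadbeef")
        for pa, pb in zip(paths_a, paths_b):
            assert pa.read_bytes() == pb.read_bytes()

    def test_provenance_header_present(self, small_cohort, tmp_path):
        bundle = small_cohort["result"].report_bundle(n_boot=20, seed=5)
        (path, *_rest) = render(bundle, tmp_path, provenance="config_sha256=cafe")
        first = path.read_text().splitlines()[0]
        assert first.startswith("# icuamc") and "config_sha256=cafe" in first

    def test_quality_summary_shares(self, small_cohort):
        bundle = small_cohort["result"].report_bundle(n_boot=20, seed=5)
        quality = bundle.quality_summary.set_index("item")["value"]
        n_doses = quality["doses_total"]
        n_missing = quality["doses_missing_atc"]
        assert quality["doses_missing_atc_per_mille"] == per_mille(n_missing, n_doses)
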