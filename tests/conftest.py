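"""Shared fixtures: record factories and a small synthetic cohort."""

from __future__ import annotations

import json
from datetime import datetime, timedelta

import pytest
from hypothesis import HealthCheck, settings

from icuamc import run_pipeline, synthdata
from icuamc.ingest import AdministrationRecord, AdmissionRecord
from icuamc.registry import AtcRegistry

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

T0 = datetime(2019, 3, 1, 8, 0)


@pytest.fixture(scope="session")
def registry() -> AtcRegistry:
    return AtcRegistry.bundled()


@pytest.fixture()
def make_admission():
    counter = iter(range(1, 10_000))

    def factory(**overrides) -> AdmissionRecord:
        i = next(counter)
        fields = dict(
            admission_id=f"A{i:04d}",
            patient_id=overrides.pop("patient_id", f"P{i:04d}"),
            unit_id="ICU-T",
            care_level="tertiary",
            admit_ts=T0,
            discharge_ts=T0 + timedelta(days=2),
            age_years=60,
            sex="male",
            referring_clinic="internal_medicine",
            saps3_score=55,
            saps3_emr=0.12,
            died_in_icu=False,
            died_within_30d=False,
        )
        fields.update(overrides)
        return AdmissionRecord(**fields)

    return factory


@pytest.fixture()
def make_dose():
    counter = iter(range(1, 100_000))

    def factory(admission_id: str, timestamp: datetime, atc_code: str = "J01DD04",
                amount: float = 2.0, amount_unit: str = "g", route: str = "IV",
                ) -> AdministrationRecord:
        return AdministrationRecord(
            record_id=f"D{next(counter):05d}",
            admission_id=admission_id,
            timestamp=timestamp,
            atc_code=atc_code,
            amount=amount,
            amount_unit=amount_unit,
            route=route,
        )

    return factory


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A seeded 400-patient cohort: file paths, pipeline result and truth."""
    outdir = tmp_path_factory.mktemp("cohort")
    config = synthdata.default_config(seed=11, n_patients=400)
    paths = synthdata.generate(config, outdir)
    result = run_pipeline(paths["admissions"], paths["administrations"],
                          paths["dispensing"])
    truth = json.loads(paths["truth"].read_text())
    return {"paths": paths, "result": result, "truth": truth, "config": config}
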