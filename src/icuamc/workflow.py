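"""End-to-end orchestration: raw CSVs in, analysis objects out.

Thin glue over the domain modules so the command-line interface, the test
suite and ad-hoc analyses all run the identical pipeline:

    read → validate → adult filter → dose linkage → episodes →
    therapy days → metrics → exposure → outcomes → reports / trend
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import episodes as episodes_mod
from . import exposure as exposure_mod
from . import ingest, metrics, outcomes, reporting, trend
from .issues import IssueLog
from .registry import AtcRegistry


@dataclass
class PipelineResult:
    """Everything the reports need, computed once."""

    admissions: list
    minors_excluded: int
    minors_patient_days: float
    episodes: list
    linked: dict
    therapy_days: list
    adm_frame: pd.DataFrame
    class_frame: pd.DataFrame
    exposures: dict
    dispensing: list
    registry: AtcRegistry
    logs: dict[str, IssueLog] = field(default_factory=dict)

    @property
    def patient_days(self) -> float:
        return float(self.adm_frame["patient_days"].sum()) if len(self.adm_frame) else 0.0

    def stratum_table(self, by: list[str]) -> pd.DataFrame:
        return metrics.aggregate(self.adm_frame, by)

    def exposure_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return exposure_mod.exposure_table(self.episodes, self.exposures)

    def outcome_summaries(self):
        return outcomes.exposure_mortality(self.episodes, self.exposures)

    def daily_series(self, date_range=None, overlay=None) -> pd.DataFrame:
        return trend.daily_series(self.admissions, self.therapy_days,
                                  date_range=date_range, overlay=overlay)

    def report_bundle(self, n_boot: int = reporting.BOOTSTRAP_REPS,
                      seed: int = 0) -> reporting.ReportBundle:
        _total_ddd, excluded_share = metrics.ddd_administered(self.linked, self.registry)
        n_doses = sum(len(v) for v in self.linked.values())
        n_missing = sum(1 for doses in self.linked.values()
                        for d in doses if d.atc_code is None)
        return reporting.ReportBundle(
            population_table=reporting.population_table(self.episodes),
            clinic_table=reporting.clinic_table(self.episodes),
            class_consumption=reporting.class_consumption(self.class_frame, self.adm_frame),
            clinic_consumption=reporting.clinic_consumption(self.adm_frame,
                                                            n_boot=n_boot, seed=seed),
            metric_comparison=reporting.metric_comparison(
                self.class_frame, self.dispensing, self.registry,
                patient_days=self.patient_days,
                minors_count=self.minors_excluded,
                minors_patient_days=self.minors_patient_days,
            ),
            quality_summary=reporting.quality_summary(
                self.logs, n_doses=n_doses, n_missing_atc=n_missing,
                undefined_ddd_dot_share=excluded_share,
                minors_excluded=self.minors_excluded,
            ),
        )


def run_pipeline(
    admissions_path: str | Path,
    administrations_path: str | Path,
    dispensing_path: str | Path | None = None,
    registry: AtcRegistry | None = None,
    gap_threshold_hours: float = episodes_mod.GAP_THRESHOLD_HOURS,
    ingest_config: ingest.IngestConfig | None = None,
) -> PipelineResult:
    registry = registry or AtcRegistry.bundled()
    admissions, adm_log = ingest.read_admissions(admissions_path, ingest_config)
    doses, dose_log = ingest.read_administrations(administrations_path, ingest_config)
    dispensing: list = []
    logs = {"admissions": adm_log, "administrations": dose_log}
    if dispensing_path is not None:
        dispensing, disp_log = ingest.read_dispensing(dispensing_path, ingest_config)
        logs["dispensing"] = disp_log

    adults, minors_excluded = episodes_mod.filter_adults(admissions)
    minors = [a for a in admissions if a.age_years < 18]
    linked, link_log = ingest.link_records(adults, doses, ingest_config)
    logs["linkage"] = link_log
    episode_log = IssueLog()
    eps = episodes_mod.build_episodes(adults, gap_threshold_hours, episode_log)
    logs["episodes"] = episode_log
    kept_ids = {a.admission_id for ep in eps for a in ep.admissions}
    adults = [a for a in adults if a.admission_id in kept_ids]

    days = metrics.therapy_days(linked, registry)
    adm_frame = metrics.admission_metrics(adults, days, linked, registry)
    class_frame = metrics.class_metrics(adults, days, linked, registry, by=("care_level",))
    exposures = exposure_mod.classify_all(eps, days)
    return PipelineResult(
        admissions=adults,
        minors_excluded=minors_excluded,
        minors_patient_days=episodes_mod.patient_days(minors),
        episodes=eps,
        linked=linked,
        therapy_days=days,
        adm_frame=adm_frame,
        class_frame=class_frame,
        exposures=exposures,
        dispensing=dispensing,
        registry=registry,
        logs=logs,
    )
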