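"""Analysis units: adult filter, 48-hour readmission merge, patient-days.

An *episode* is one continuous intensive-care event.  A readmission starting
less than 48 hours (strictly) after the previous discharge belongs to the same
episode; a gap of exactly 48 hours starts a new one.  Transfers between units
stay separate admissions — drug doses always attribute to the administering
unit — but can still share an episode when the gap is short.  The gap between
a discharge and a merged readmission contributes neither length of stay nor
patient-days: only ICU care time divides consumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ingest import AdmissionRecord
from .issues import IssueLog

GAP_THRESHOLD_HOURS = 48.0
LOS_BUCKET_DAYS = 2.0  # ">48 hours" boundary, strict


@dataclass(frozen=True)
class Episode:
    """One intensive-care episode: ordered member admissions plus summaries."""

    episode_id: str
    patient_id: str
    admissions: tuple[AdmissionRecord, ...]
    episode_start: object
    episode_end: object
    los_days: float
    care_level_of_record: str
    died_in_icu: bool | None
    died_within_30d: bool | None

    @property
    def los_gt_48h(self) -> bool:
        return self.los_days > LOS_BUCKET_DAYS

    @property
    def admission_ids(self) -> tuple[str, ...]:
        return tuple(a.admission_id for a in self.admissions)

    @property
    def saps3_score(self) -> int | None:
        """Severity at the start of the episode (first admission)."""
        return self.admissions[0].saps3_score

    @property
    def saps3_emr(self) -> float | None:
        return self.admissions[0].saps3_emr


def filter_adults(
    admissions: list[AdmissionRecord], log: IssueLog | None = None
) -> tuple[list[AdmissionRecord], int]:
    """Keep admissions aged 18 or older; report the excluded count.

    The excluded count matters downstream: pharmacy dispensing covers the
    whole medicine shelf, so the under-18 admissions it may have served are
    echoed in the metric-comparison report.
    """
    kept = [a for a in admissions if a.age_years >= 18]
    return kept, len(admissions) - len(kept)


def build_episodes(
    admissions: list[AdmissionRecord],
    gap_threshold_hours: float = GAP_THRESHOLD_HOURS,
    log: IssueLog | None = None,
) -> list[Episode]:
    """Partition admissions into episodes by the readmission-gap rule.

    Within a patient, consecutive admissions (ordered by admission time)
    whose discharge→admission gap is strictly below the threshold share an
    episode.  Member admissions are never fused: unit-level attribution of
    doses is preserved.  An admission overlapping the previous one of the
    same patient is rejected (identifiers are assumed clean; overlap means a
    data error).
    """
    log = log if log is not None else IssueLog()
    by_patient: dict[str, list[AdmissionRecord]] = {}
    for adm in admissions:
        by_patient.setdefault(adm.patient_id, []).append(adm)

    episodes: list[Episode] = []
    for patient_id in sorted(by_patient):
        ordered = sorted(by_patient[patient_id], key=lambda a: (a.admit_ts, a.admission_id))
        accepted: list[AdmissionRecord] = []
        for adm in ordered:
            if accepted and adm.admit_ts < accepted[-1].discharge_ts:
                log.reject(adm.admission_id, "overlapping_admission",
                           f"overlaps admission {accepted[-1].admission_id} of patient {patient_id}")
                continue
            accepted.append(adm)
        group: list[AdmissionRecord] = []
        for adm in accepted:
            if group:
                gap_hours = (adm.admit_ts - group[-1].discharge_ts).total_seconds() / 3600.0
                if gap_hours < gap_threshold_hours:
                    group.append(adm)
                    continue
                episodes.append(_make_episode(group))
            group = [adm]
        if group:
            episodes.append(_make_episode(group))
    episodes.sort(key=lambda e: (e.episode_start, e.patient_id))
    return [_with_id(e, i) for i, e in enumerate(episodes, start=1)]


def _make_episode(group: list[AdmissionRecord]) -> Episode:
    died_icu_values = [a.died_in_icu for a in group if a.died_in_icu is not None]
    return Episode(
        episode_id="",  # assigned after global ordering
        patient_id=group[0].patient_id,
        admissions=tuple(group),
        episode_start=group[0].admit_ts,
        episode_end=group[-1].discharge_ts,
        los_days=patient_days(group),
        care_level_of_record=group[0].care_level,
        died_in_icu=any(died_icu_values) if died_icu_values else None,
        died_within_30d=group[-1].died_within_30d,
    )


def _with_id(episode: Episode, number: int) -> Episode:
    object.__setattr__(episode, "episode_id", f"E{number:06d}")
    return episode


def patient_days(admissions_or_episode) -> float:
    """Fractional patient-days: Σ (discharge − admit) hours / 24, unrounded."""
    if isinstance(admissions_or_episode, Episode):
        admissions = admissions_or_episode.admissions
    else:
        admissions = admissions_or_episode
    total_seconds = sum(
        (a.discharge_ts - a.admit_ts).total_seconds() for a in admissions
    )
    return total_seconds / 86400.0


def episodes_frame(episodes: list[Episode]) -> pd.DataFrame:
    """Tabular export of the episode partition."""
    rows = []
    for e in episodes:
        rows.append({
            "episode_id": e.episode_id,
            "patient_id": e.patient_id,
            "n_admissions": len(e.admissions),
            "episode_start": e.episode_start.isoformat(),
            "episode_end": e.episode_end.isoformat(),
            "los_days": e.los_days,
            "care_level_of_record": e.care_level_of_record,
            "died_in_icu": e.died_in_icu,
            "died_within_30d": e.died_within_30d,
        })
    return pd.DataFrame(rows, columns=[
        "episode_id", "patient_id", "n_admissions", "episode_start", "episode_end",
        "los_days", "care_level_of_record", "died_in_icu", "died_within_30d",
    ])


def write_episodes(episodes: list[Episode], path: str | Path) -> None:
    episodes_frame(episodes).to_csv(path, index=False)
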