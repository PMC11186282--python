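"""Readers for the three CSV inputs of the surveillance pipeline.

The exchange boundary is deliberately plain: three UTF-8 CSV files with
ISO-8601 timestamps — one row per ICU admission, one row per signed drug dose,
and (optionally) one row per pharmacy dispensing period.  Each reader validates
rows against the record invariants; a row that violates them is excluded and
logged with severity ``reject``, while recoverable oddities (unknown referring
clinic, missing ATC code) are logged with severity ``warn`` and kept.  A
missing file or a missing mandatory column is fatal and raises.

Timestamps without a timezone are interpreted as local clinical (wall-clock)
time; calendar-day metrics downstream follow wall-clock dates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import pandas as pd

from .issues import IssueLog

ATC_PATTERN = re.compile(r"^[A-V][0-9]{2}[A-Z]{2}[0-9]{2}$")

AMOUNT_UNITS = ("mg", "g", "MU")
ROUTES = ("IV", "PO", "INH", "other")
CARE_LEVELS = ("secondary", "tertiary")
SEXES = ("female", "male", "other/unknown")
REFERRING_CLINICS = (
    "internal_medicine",
    "general_surgery",
    "neurosurgery",
    "infectious_diseases",
    "neurology",
    "orthopedic_surgery",
    "oncology_haematology",
    "other",
)

ADMISSION_COLUMNS = [
    "admission_id", "patient_id", "unit_id", "care_level", "admit_ts",
    "discharge_ts", "age_years", "sex", "referring_clinic", "saps3_score",
    "saps3_emr", "imv_hours", "crrt_hours", "cvc_hours", "died_in_icu",
    "died_within_30d",
]
ADMINISTRATION_COLUMNS = [
    "record_id", "admission_id", "timestamp", "atc_code", "amount",
    "amount_unit", "route",
]
DISPENSING_COLUMNS = [
    "unit_id", "period_start", "period_end", "atc_code", "amount", "amount_unit",
]


@dataclass(frozen=True)
class AdministrationRecord:
    """One signed drug dose: who, when, what, how much, which route."""

    record_id: str
    admission_id: str
    timestamp: datetime
    atc_code: str | None
    amount: float
    amount_unit: str
    route: str


@dataclass(frozen=True)
class AdmissionRecord:
    """One ICU admission with demographics, severity and outcome fields."""

    admission_id: str
    patient_id: str
    unit_id: str
    care_level: str
    admit_ts: datetime
    discharge_ts: datetime
    age_years: int
    sex: str
    referring_clinic: str
    saps3_score: int | None = None
    saps3_emr: float | None = None
    imv_hours: float | None = None
    crrt_hours: float | None = None
    cvc_hours: float | None = None
    died_in_icu: bool | None = None
    died_within_30d: bool | None = None

    @property
    def los_days(self) -> float:
        """Length of stay in fractional patient-days (hours / 24)."""
        return (self.discharge_ts - self.admit_ts).total_seconds() / 86400.0


@dataclass(frozen=True)
class DispensingRecord:
    """Antimicrobials supplied to a unit's medicine shelf over a period."""

    unit_id: str
    period_start: date
    period_end: date
    atc_code: str
    amount: float
    amount_unit: str


@dataclass(frozen=True)
class IngestConfig:
    """Tunable ingest behaviour; defaults reproduce the standard run."""

    clamp_tolerance_hours: float = 1.0
    registry: object | None = None  # AtcRegistry for unknown-code warnings


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    return frame


def _parse_ts(raw: str) -> datetime:
    ts = datetime.fromisoformat(raw.strip())
    if ts.tzinfo is not None:  # wall-clock semantics: drop the offset
        ts = ts.replace(tzinfo=None)
    return ts


def _parse_float(raw: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    value = float(raw)
    if math.isnan(value):
        return None
    return value


def _parse_bool(raw: str) -> bool | None:
    raw = raw.strip().lower()
    if raw == "":
        return None
    if raw in ("true", "1", "yes"):
        return True
    if raw in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def read_admissions(
    path: str | Path, config: IngestConfig | None = None
) -> tuple[list[AdmissionRecord], IssueLog]:
    """Read and validate admissions.csv.

    Returns the well-formed records and an issue log; rows violating the
    record invariants (unparsable timestamps, discharge before admission,
    negative age, out-of-range mortality probability ...) are rejected and
    logged.  Unknown referring-clinic labels are mapped to ``other`` with a
    warning, matching the explicit "Other" reporting stratum.
    """
    frame = _read_csv(path, ADMISSION_COLUMNS)
    records: list[AdmissionRecord] = []
    log = IssueLog()
    seen: set[str] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        loc = f"{Path(path).name}:{idx}"
        try:
            admission_id = row.admission_id.strip()
            if not admission_id:
                raise ValueError("empty admission_id")
            if admission_id in seen:
                raise ValueError(f"duplicate admission_id {admission_id}")
            care_level = row.care_level.strip()
            if care_level not in CARE_LEVELS:
                raise ValueError(f"unknown care_level {care_level!r}")
            admit_ts = _parse_ts(row.admit_ts)
            discharge_ts = _parse_ts(row.discharge_ts)
            if not admit_ts < discharge_ts:
                raise ValueError("admit_ts must precede discharge_ts")
            age_raw = row.age_years.strip()
            if age_raw == "":
                raise ValueError("age_years is mandatory")
            age_years = int(age_raw)
            if age_years < 0:
                raise ValueError("age_years must be >= 0")
            sex = row.sex.strip()
            if sex not in SEXES:
                sex = "other/unknown"
            clinic = row.referring_clinic.strip()
            if clinic not in REFERRING_CLINICS:
                log.warn(loc, "unknown_clinic", f"referring_clinic {clinic!r} mapped to 'other'")
                clinic = "other"
            saps3_raw = row.saps3_score.strip()
            saps3_score = int(saps3_raw) if saps3_raw else None
            saps3_emr = _parse_float(row.saps3_emr)
            if saps3_emr is not None and not 0.0 <= saps3_emr <= 1.0:
                raise ValueError(f"saps3_emr {saps3_emr} outside [0, 1]")
            hours = {}
            for name in ("imv_hours", "crrt_hours", "cvc_hours"):
                value = _parse_float(getattr(row, name))
                if value is not None and value < 0:
                    raise ValueError(f"{name} must be non-negative")
                hours[name] = value
            record = AdmissionRecord(
                admission_id=admission_id,
                patient_id=row.patient_id.strip(),
                unit_id=row.unit_id.strip(),
                care_level=care_level,
                admit_ts=admit_ts,
                discharge_ts=discharge_ts,
                age_years=age_years,
                sex=sex,
                referring_clinic=clinic,
                saps3_score=saps3_score,
                saps3_emr=saps3_emr,
                died_in_icu=_parse_bool(row.died_in_icu),
                died_within_30d=_parse_bool(row.died_within_30d),
                **hours,
            )
        except (ValueError, TypeError) as exc:
            log.reject(loc, "invalid_admission", str(exc))
            continue
        seen.add(record.admission_id)
        records.append(record)
    return records, log


def read_administrations(
    path: str | Path, config: IngestConfig | None = None
) -> tuple[list[AdministrationRecord], IssueLog]:
    """Read and validate administrations.csv.

    A dose without an ATC code is kept (it may still be attributable to the
    antimicrobial set through a registry override) but logged as a warning,
    because it cannot be linked to the day-of-therapy variables downstream.
    """
    frame = _read_csv(path, ADMINISTRATION_COLUMNS)
    records: list[AdministrationRecord] = []
    log = IssueLog()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        loc = f"{Path(path).name}:{idx}"
        try:
            record_id = row.record_id.strip()
            admission_id = row.admission_id.strip()
            if not record_id or not admission_id:
                raise ValueError("empty record_id or admission_id")
            timestamp = _parse_ts(row.timestamp)
            atc = row.atc_code.strip() or None
            if atc is not None and not ATC_PATTERN.match(atc):
                raise ValueError(f"malformed ATC code {atc!r}")
            amount = _parse_float(row.amount)
            if amount is None:
                raise ValueError("amount is mandatory")
            if amount < 0:
                raise ValueError("amount must be non-negative")
            unit = row.amount_unit.strip()
            if unit not in AMOUNT_UNITS:
                raise ValueError(f"unknown amount_unit {unit!r}")
            route = row.route.strip()
            if route not in ROUTES:
                route = "other"
        except (ValueError, TypeError) as exc:
            log.reject(loc, "invalid_administration", str(exc))
            continue
        if atc is None:
            log.warn(loc, "missing_atc", f"dose {record_id}: missing ATC linkage")
        elif config is not None and config.registry is not None and atc not in config.registry:
            log.warn(loc, "unknown_atc",
                     f"dose {record_id}: ATC {atc} not in the surveilled registry")
        records.append(
            AdministrationRecord(
                record_id=record_id,
                admission_id=admission_id,
                timestamp=timestamp,
                atc_code=atc,
                amount=amount,
                amount_unit=unit,
                route=route,
            )
        )
    return records, log


def read_dispensing(
    path: str | Path, config: IngestConfig | None = None
) -> tuple[list[DispensingRecord], IssueLog]:
    """Read pharmacy dispensing periods (optional comparison input)."""
    frame = _read_csv(path, DISPENSING_COLUMNS)
    records: list[DispensingRecord] = []
    log = IssueLog()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        loc = f"{Path(path).name}:{idx}"
        try:
            start = date.fromisoformat(row.period_start.strip())
            end = date.fromisoformat(row.period_end.strip())
            if start > end:
                raise ValueError("period_start after period_end")
            atc = row.atc_code.strip()
            if not ATC_PATTERN.match(atc):
                raise ValueError(f"malformed ATC code {atc!r}")
            amount = _parse_float(row.amount)
            if amount is None or amount < 0:
                raise ValueError("amount must be a non-negative number")
            unit = row.amount_unit.strip()
            if unit not in AMOUNT_UNITS:
                raise ValueError(f"unknown amount_unit {unit!r}")
        except (ValueError, TypeError) as exc:
            log.reject(loc, "invalid_dispensing", str(exc))
            continue
        records.append(DispensingRecord(row.unit_id.strip(), start, end, atc, amount, unit))
    return records, log


def link_records(
    admissions: list[AdmissionRecord],
    administrations: list[AdministrationRecord],
    config: IngestConfig | None = None,
) -> tuple[dict[str, list[AdministrationRecord]], IssueLog]:
    """Attach every dose to its admission, clamping stray timestamps.

    Signing delays are common in electronic records, so a dose stamped
    outside the admission interval is clamped to the interval edge and kept
    rather than dropped; the warning code records whether the deviation was
    within the configured tolerance (default 1 h).  Doses referencing an
    unknown admission are rejected.
    """
    config = config or IngestConfig()
    tolerance = timedelta(hours=config.clamp_tolerance_hours)
    by_id = {a.admission_id: a for a in admissions}
    linked: dict[str, list[AdministrationRecord]] = {a.admission_id: [] for a in admissions}
    log = IssueLog()
    for dose in administrations:
        admission = by_id.get(dose.admission_id)
        if admission is None:
            log.reject(dose.record_id, "orphan_dose", f"no admission {dose.admission_id!r}")
            continue
        ts = dose.timestamp
        if ts < admission.admit_ts or ts > admission.discharge_ts:
            clamped = min(max(ts, admission.admit_ts), admission.discharge_ts)
            deviation = abs(ts - clamped)
            code = (
                "clamped_within_tolerance"
                if deviation <= tolerance
                else "clamped_beyond_tolerance"
            )
            log.warn(
                dose.record_id,
                code,
                f"dose timestamp {ts.isoformat()} outside admission interval by "
                f"{deviation.total_seconds() / 3600.0:.2f} h; clamped",
            )
            dose = replace(dose, timestamp=clamped)
        linked[dose.admission_id].append(dose)
    for doses in linked.values():
        doses.sort(key=lambda d: (d.timestamp, d.record_id))
    return linked, log


def write_admissions(records: list[AdmissionRecord], path: str | Path) -> None:
    """Write records back in the canonical column order (round-trip safe)."""
    rows = []
    for r in records:
        rows.append({
            "admission_id": r.admission_id,
            "patient_id": r.patient_id,
            "unit_id": r.unit_id,
            "care_level": r.care_level,
            "admit_ts": r.admit_ts.isoformat(),
            "discharge_ts": r.discharge_ts.isoformat(),
            "age_years": r.age_years,
            "sex": r.sex,
            "referring_clinic": r.referring_clinic,
            "saps3_score": "" if r.saps3_score is None else r.saps3_score,
            "saps3_emr": "" if r.saps3_emr is None else repr(r.saps3_emr),
            "imv_hours": "" if r.imv_hours is None else repr(r.imv_hours),
            "crrt_hours": "" if r.crrt_hours is None else repr(r.crrt_hours),
            "cvc_hours": "" if r.cvc_hours is None else repr(r.cvc_hours),
            "died_in_icu": "" if r.died_in_icu is None else str(r.died_in_icu).lower(),
            "died_within_30d": "" if r.died_within_30d is None else str(r.died_within_30d).lower(),
        })
    pd.DataFrame(rows, columns=ADMISSION_COLUMNS).to_csv(path, index=False)


def write_administrations(records: list[AdministrationRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "record_id": r.record_id,
            "admission_id": r.admission_id,
            "timestamp": r.timestamp.isoformat(),
            "atc_code": r.atc_code or "",
            "amount": repr(r.amount),
            "amount_unit": r.amount_unit,
            "route": r.route,
        })
    pd.DataFrame(rows, columns=ADMINISTRATION_COLUMNS).to_csv(path, index=False)
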