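"""The three consumption metrics: DOT, LOT and administered DDD.

Definitions (the field's standard ones):

* **DOT** — days of therapy.  One DOT per distinct antimicrobial agent per
  calendar day per admission, regardless of dose: a patient on two agents the
  same day accrues two DOT.
* **LOT** — length of therapy.  The number of calendar days with at least one
  antimicrobial administration, irrespective of how many agents.
* **administered DDD** — administered substance weight divided by the WHO
  defined daily dose for the agent and route.

Day attribution is by the dose's wall-clock calendar date (a dose clamped at
ingest uses its clamped timestamp).  Drugs without a usable DDD contribute to
DOT and LOT but are excluded from DDD sums; their DOT share is reported so the
omission is visible.  All consumption is normalised per 1000 patient-days.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

from .ingest import AdministrationRecord, AdmissionRecord
from .registry import AtcRegistry

AGE_BANDS = ((18, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 200))

STRATUM_KEYS = ("care_level", "unit_id", "referring_clinic", "sex", "age_band", "year")


def age_band(age_years: int) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age_years <= hi:
            return f"{lo}+" if hi >= 200 else f"{lo}-{hi}"
    return "<18"


@dataclass(frozen=True)
class DailyTherapyDay:
    """One (admission, calendar date) with ≥1 antimicrobial dose."""

    admission_id: str
    date: date
    agents: frozenset[str]   # distinct ATC codes that date
    classes: frozenset[str]  # distinct drug classes, via the registry

    def __post_init__(self) -> None:
        if not self.agents:
            raise ValueError("a therapy day must have at least one agent")


def therapy_days(
    linked: dict[str, list[AdministrationRecord]], registry: AtcRegistry
) -> list[DailyTherapyDay]:
    """Identify, per admission and calendar date, the distinct agents given.

    Only doses whose ATC code resolves in the registry count (registry
    membership defines the surveilled antimicrobial set); other doses are
    ignored here and surface in the data-quality report instead.
    """
    agents_by_key: dict[tuple[str, date], set[str]] = {}
    for admission_id, doses in linked.items():
        for dose in doses:
            if dose.atc_code is None or dose.atc_code not in registry:
                continue
            agents_by_key.setdefault((admission_id, dose.timestamp.date()), set()).add(dose.atc_code)
    days = [
        DailyTherapyDay(
            admission_id=admission_id,
            date=day,
            agents=frozenset(agents),
            classes=frozenset(registry.class_of(code) for code in agents),
        )
        for (admission_id, day), agents in agents_by_key.items()
    ]
    days.sort(key=lambda d: (d.admission_id, d.date))
    return days


def dot(days: list[DailyTherapyDay]) -> int:
    """Days of therapy: Σ over therapy days of the distinct-agent count."""
    return sum(len(d.agents) for d in days)


def lot(days: list[DailyTherapyDay]) -> int:
    """Length of therapy: number of distinct (admission, date) therapy days."""
    return len(days)


def ddd_administered(
    linked: dict[str, list[AdministrationRecord]], registry: AtcRegistry
) -> tuple[float, float]:
    """Total administered DDD and the DOT share it could not cover.

    Returns ``(ddd_total, excluded_dot_share)`` where the share is the
    fraction of DOT attributable to agent-days none of whose doses could be
    converted (undefined DDD, or incommensurable units such as MU against a
    mass-denominated index).  Share 0.0 when there is no DOT at all.
    """
    total = 0.0
    convertible: dict[tuple[str, date, str], bool] = {}
    for admission_id, doses in linked.items():
        for dose in doses:
            if dose.atc_code is None or dose.atc_code not in registry:
                continue
            key = (admission_id, dose.timestamp.date(), dose.atc_code)
            value = registry.ddd_equivalents(dose.atc_code, dose.route, dose.amount, dose.amount_unit)
            if value is None:
                convertible.setdefault(key, False)
            else:
                total += value
                convertible[key] = True
    n_triples = len(convertible)
    excluded = sum(1 for ok in convertible.values() if not ok)
    share = excluded / n_triples if n_triples else 0.0
    return total, share


def rate_per_1000_pd(total: float, patient_days: float) -> float | None:
    """Normalise a consumption total per 1000 patient-days.

    Undefined (``None``) when the denominator is zero — a stratum with no
    care time has no meaningful rate, and zero would be misleading.
    """
    if patient_days < 0:
        raise ValueError("patient_days must be non-negative")
    if patient_days == 0:
        return None
    return total / patient_days * 1000.0


@dataclass(frozen=True)
class StratumMetrics:
    """Consumption totals and denominators for one stratum.

    Rates and ratios are derived on demand, never stored, so every printed
    rate traces back to exactly these totals.
    """

    key: dict
    dot: int
    lot: int
    ddd_administered: float
    patient_days: float
    n_admissions: int
    n_amu_admissions: int
    ddd_dispensed: float | None = None

    def __post_init__(self) -> None:
        if not (self.dot >= self.lot >= 0):
            raise ValueError("requires dot >= lot >= 0")
        if min(self.ddd_administered, self.patient_days, self.n_admissions,
               self.n_amu_admissions) < 0:
            raise ValueError("totals must be non-negative")

    @property
    def dot_rate(self) -> float | None:
        return rate_per_1000_pd(self.dot, self.patient_days)

    @property
    def lot_rate(self) -> float | None:
        return rate_per_1000_pd(self.lot, self.patient_days)

    @property
    def ddd_rate(self) -> float | None:
        return rate_per_1000_pd(self.ddd_administered, self.patient_days)


def derived_ratios(stratum: StratumMetrics) -> dict[str, float | None]:
    """LOT per admission, LOT per antimicrobial-use admission, DOT/LOT.

    DOT/LOT measures simultaneous multi-agent exposure; it is undefined
    (``None``), never zero, when there is no therapy at all.
    """
    return {
        "lot_per_admission": (stratum.lot / stratum.n_admissions
                              if stratum.n_admissions else None),
        "lot_per_amu_admission": (stratum.lot / stratum.n_amu_admissions
                                  if stratum.n_amu_admissions else None),
        "dot_lot_ratio": stratum.dot / stratum.lot if stratum.lot else None,
    }


def admission_metrics(
    admissions: list[AdmissionRecord],
    days: list[DailyTherapyDay],
    linked: dict[str, list[AdministrationRecord]],
    registry: AtcRegistry,
) -> pd.DataFrame:
    """One row per admission: stratum attributes plus metric totals.

    This frame is the single source of truth for every stratified report;
    group-bys over it are guaranteed to conserve the grand totals.
    """
    dot_by_adm: dict[str, int] = {}
    lot_by_adm: dict[str, int] = {}
    for d in days:
        dot_by_adm[d.admission_id] = dot_by_adm.get(d.admission_id, 0) + len(d.agents)
        lot_by_adm[d.admission_id] = lot_by_adm.get(d.admission_id, 0) + 1
    rows = []
    for adm in admissions:
        sub = {adm.admission_id: linked.get(adm.admission_id, [])}
        ddd_total, _ = ddd_administered(sub, registry)
        rows.append({
            "admission_id": adm.admission_id,
            "patient_id": adm.patient_id,
            "unit_id": adm.unit_id,
            "care_level": adm.care_level,
            "referring_clinic": adm.referring_clinic,
            "sex": adm.sex,
            "age_band": age_band(adm.age_years),
            "year": adm.admit_ts.year,
            "dot": dot_by_adm.get(adm.admission_id, 0),
            "lot": lot_by_adm.get(adm.admission_id, 0),
            "ddd_administered": ddd_total,
            "patient_days": adm.los_days,
            "amu": dot_by_adm.get(adm.admission_id, 0) > 0,
        })
    return pd.DataFrame(rows)


def aggregate(frame: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Aggregate the per-admission frame over stratum columns.

    Returns one row per stratum with totals, denominators and the derived
    rate/ratio columns of the standard export.
    """
    if frame.empty:
        columns = list(by) + [
            "dot", "lot", "ddd_administered", "patient_days", "n_admissions",
            "n_amu_admissions", "dot_rate", "lot_rate", "ddd_rate",
            "dot_lot_ratio", "lot_per_admission", "lot_per_amu_admission",
        ]
        return pd.DataFrame(columns=columns)
    grouped = frame.groupby(list(by), as_index=False, observed=True).agg(
        dot=("dot", "sum"),
        lot=("lot", "sum"),
        ddd_administered=("ddd_administered", "sum"),
        patient_days=("patient_days", "sum"),
        n_admissions=("admission_id", "count"),
        n_amu_admissions=("amu", "sum"),
    )
    out_rows = []
    for row in grouped.to_dict("records"):
        stratum = StratumMetrics(
            key={k: row[k] for k in by},
            dot=int(row["dot"]),
            lot=int(row["lot"]),
            ddd_administered=float(row["ddd_administered"]),
            patient_days=float(row["patient_days"]),
            n_admissions=int(row["n_admissions"]),
            n_amu_admissions=int(row["n_amu_admissions"]),
        )
        ratios = derived_ratios(stratum)
        row.update({
            "n_amu_admissions": int(row["n_amu_admissions"]),
            "dot_rate": stratum.dot_rate,
            "lot_rate": stratum.lot_rate,
            "ddd_rate": stratum.ddd_rate,
            **ratios,
        })
        out_rows.append(row)
    return pd.DataFrame(out_rows).sort_values(list(by)).reset_index(drop=True)


def class_metrics(
    admissions: list[AdmissionRecord],
    days: list[DailyTherapyDay],
    linked: dict[str, list[AdministrationRecord]],
    registry: AtcRegistry,
    by: tuple[str, ...] = ("care_level",),
) -> pd.DataFrame:
    """Per-(stratum, class) DOT/LOT/DDD and per-(stratum, agent) detail.

    Classes partition the agent set, so per-class DOT sums to the stratum
    total; per-class LOT does not (a day can hold several classes) and is
    reported as class-days instead.
    """
    attrs = {a.admission_id: a for a in admissions}

    def stratum_of(admission_id: str) -> tuple:
        adm = attrs[admission_id]
        values = []
        for k in by:
            if k == "age_band":
                values.append(age_band(adm.age_years))
            elif k == "year":
                values.append(adm.admit_ts.year)
            else:
                values.append(getattr(adm, k))
        return tuple(values)

    dot_rows: dict[tuple, dict] = {}
    for d in days:
        if d.admission_id not in attrs:
            continue
        stratum = stratum_of(d.admission_id)
        for agent in d.agents:
            key = stratum + (registry.class_of(agent), agent)
            entry = dot_rows.setdefault(key, {"dot": 0, "ddd_administered": 0.0})
            entry["dot"] += 1
    for admission_id, doses in linked.items():
        if admission_id not in attrs:
            continue
        stratum = stratum_of(admission_id)
        for dose in doses:
            if dose.atc_code is None or dose.atc_code not in registry:
                continue
            value = registry.ddd_equivalents(dose.atc_code, dose.route, dose.amount, dose.amount_unit)
            if value is None:
                continue
            key = stratum + (registry.class_of(dose.atc_code), dose.atc_code)
            entry = dot_rows.setdefault(key, {"dot": 0, "ddd_administered": 0.0})
            entry["ddd_administered"] += value
    rows = []
    for key in sorted(dot_rows, key=lambda k: tuple(str(x) for x in k)):
        entry = dot_rows[key]
        row = dict(zip(by, key[:-2]))
        row["class_label"] = key[-2]
        row["atc_code"] = key[-1]
        row["substance_name"] = registry.lookup(key[-1]).substance_name
        row.update(entry)
        rows.append(row)
    columns = list(by) + ["class_label", "atc_code", "substance_name", "dot", "ddd_administered"]
    return pd.DataFrame(rows, columns=columns)
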