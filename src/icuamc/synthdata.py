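"""Synthetic ICU admission / medication-administration / dispensing data.

The generator emulates the statistical structure of a four-year, three-unit
general-ICU cohort in a low-consumption setting: care-level and referring-
clinic mix, log-normal length of stay per clinic, severity scores with a
logistic transform to a predicted mortality (EMR), deaths drawn as
Bernoulli(EMR), readmissions with a gap distribution straddling the 48-hour
merge boundary, per-class prescribing hazards with course durations, dose
timestamps at nursing-round hours (to exercise calendar-day boundaries), and
pharmacy dispensing inflated relative to administration — strongly so for the
surgical-prophylaxis penicillin, whose shelf also serves patients outside the
surveilled population.

Alongside the three CSVs the generator writes ``truth.json``: per-admission
and per-episode ground-truth DOT/LOT/DDD/exposure enumerated *directly from
the doses it generated*, by its own independent code path (its own registry
parse, its own unit conversion, its own gap grouping).  The pipeline is tested
against this truth, so the generator deliberately never imports the metrics,
episodes or registry modules' logic.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

_Z_IQR = 0.6744897501960817  # standard normal 75th percentile

# (atc, route, doses/day, per-dose amount, unit, within-class weight)
_DRUGS: dict[str, list[tuple[str, str, int, float, str, float]]] = {
    "cephalosporin_3rd_gen": [("J01DD01", "IV", 3, 1.0, "g", 0.6),
                              ("J01DD04", "IV", 1, 2.0, "g", 0.3),
                              ("J01DD02", "IV", 3, 1.0, "g", 0.1)],
    "penicillin_blinh": [("J01CR05", "IV", 3, 4.0, "g", 1.0)],
    "carbapenem": [("J01DH02", "IV", 3, 1.0, "g", 1.0)],
    "glycopeptide": [("J01XA01", "IV", 2, 1.0, "g", 1.0)],
    "fluoroquinolone": [("J01MA02", "IV", 2, 0.4, "g", 0.8),
                        ("J01MA12", "IV", 1, 0.5, "g", 0.2)],
    "penicillin_narrow": [("J01CE01", "IV", 3, 1.0, "g", 1.0)],
    "penicillin_blres": [("J01CF02", "IV", 3, 2.0, "g", 1.0)],
    "aminoglycoside": [("J01GB03", "IV", 1, 0.32, "g", 1.0)],
    "macrolide": [("J01FA10", "IV", 1, 0.5, "g", 1.0)],
    "nitroimidazole": [("J01XD01", "IV", 3, 0.5, "g", 1.0)],
    "lincosamide": [("J01FF01", "IV", 3, 0.6, "g", 1.0)],
    "cephalosporin_2nd_gen": [("J01DC02", "IV", 3, 1.5, "g", 1.0)],
    "sulfonamide_trimethoprim": [("J01EE01", "IV", 2, 0.8, "g", 1.0)],
    "polymyxin": [("J01XB01", "IV", 3, 3.0, "MU", 1.0)],
    "tetracycline": [("J01AA02", "IV", 1, 0.1, "g", 1.0)],
    "triazole": [("J02AC01", "IV", 1, 0.4, "g", 1.0)],
    "echinocandin": [("J02AX06", "IV", 1, 0.1, "g", 0.5),
                     ("J02AX04", "IV", 1, 50.0, "mg", 0.5)],
    "rifamycin": [("J04AB02", "IV", 1, 0.6, "g", 1.0)],
}

_CLASS_WEIGHTS = {
    "tertiary": {
        "cephalosporin_3rd_gen": 27, "penicillin_blinh": 20, "carbapenem": 8,
        "glycopeptide": 6, "fluoroquinolone": 6, "penicillin_narrow": 6,
        "penicillin_blres": 4, "aminoglycoside": 4, "macrolide": 3,
        "nitroimidazole": 4, "lincosamide": 2, "cephalosporin_2nd_gen": 3,
        "sulfonamide_trimethoprim": 2.3, "polymyxin": 0.5, "tetracycline": 1,
        "triazole": 4.5, "echinocandin": 4.5, "rifamycin": 0.7,
    },
    "secondary": {
        "cephalosporin_3rd_gen": 17, "penicillin_blinh": 29, "carbapenem": 4,
        "glycopeptide": 4, "fluoroquinolone": 7, "penicillin_narrow": 9,
        "penicillin_blres": 2, "aminoglycoside": 5, "macrolide": 3,
        "nitroimidazole": 5, "lincosamide": 3, "cephalosporin_2nd_gen": 6,
        "sulfonamide_trimethoprim": 2, "polymyxin": 0.2, "tetracycline": 1.5,
        "triazole": 3.5, "echinocandin": 1.5, "rifamycin": 0.3,
    },
}

_CLINIC_INTENSITY = {
    "internal_medicine": 0.85, "general_surgery": 1.2, "neurosurgery": 0.55,
    "infectious_diseases": 1.45, "neurology": 0.7, "orthopedic_surgery": 1.0,
    "oncology_haematology": 2.1, "other": 0.8,
}

# reference-cohort summaries (medians with IQR, mixes, rates) the default
# configuration is calibrated to; see docs/methods.md for their provenance
REFERENCE_COHORT: dict = {
    "n_patients": 5190,
    "period": ("2018-01-01", "2021-12-31"),
    "care_level_mix": {"tertiary": 2864 / 5608, "secondary": 2744 / 5608},
    "female_fraction": 0.413,
    "age_median_iqr": (65, 48, 75),
    "minors_fraction": 787 / (5608 + 787),
    "clinic_mix": {
        "secondary": {"internal_medicine": 1883, "general_surgery": 647,
                      "orthopedic_surgery": 65, "other": 149},
        "tertiary": {"general_surgery": 810, "internal_medicine": 594,
                     "neurosurgery": 516, "infectious_diseases": 305,
                     "neurology": 243, "orthopedic_surgery": 149,
                     "oncology_haematology": 64, "other": 183},
    },
    "los_median_iqr": {
        ("secondary", "internal_medicine"): (1.0, 0.5, 2.4),
        ("secondary", "general_surgery"): (1.0, 0.5, 2.6),
        ("secondary", "orthopedic_surgery"): (1.3, 0.5, 3.2),
        ("secondary", "other"): (0.6, 0.4, 1.0),
        ("tertiary", "general_surgery"): (1.8, 0.9, 4.6),
        ("tertiary", "internal_medicine"): (0.9, 0.4, 2.1),
        ("tertiary", "neurosurgery"): (2.9, 0.9, 7.9),
        ("tertiary", "infectious_diseases"): (3.5, 1.3, 8.7),
        ("tertiary", "neurology"): (1.3, 0.6, 3.9),
        ("tertiary", "orthopedic_surgery"): (2.2, 1.1, 5.9),
        ("tertiary", "oncology_haematology"): (2.0, 1.0, 4.0),
        ("tertiary", "other"): (1.0, 0.6, 2.5),
    },
    "saps3_median_iqr": {"secondary": (51, 41, 61), "tertiary": (56, 46, 76)},
    "emr_median": {"secondary": 0.08, "tertiary": 0.14},
    "imv_fraction": {"secondary": 0.207, "tertiary": 0.572},
    "crrt_fraction": {"secondary": 0.020, "tertiary": 0.034},
}


@dataclass
class GeneratorConfig:
    """Fully seeded generating model; defaults match the reference cohort."""

    seed: int = 0
    n_patients: int = 5190
    start_date: date = date(2018, 1, 1)
    end_date: date = date(2021, 12, 31)
    tertiary_fraction: float = 2864 / 5608
    female_fraction: float = 0.413
    minors_fraction: float = 787 / (5608 + 787)
    age_split_normal: tuple[float, float, float] = (65.0, 25.2, 14.8)  # mode, sd_lo, sd_hi
    clinic_mix: dict = field(default_factory=dict)       # level -> {clinic: prob}
    los_lognormal: dict = field(default_factory=dict)    # (level, clinic) -> (mu, sigma) of ln(days)
    saps3_normal: dict = field(default_factory=dict)     # level -> (mean, sd)
    emr_slope: float = 0.115
    emr_center: dict = field(default_factory=lambda: {"secondary": 82.6, "tertiary": 71.9})
    icu_death_fraction: float = 0.44  # P(ICU death | 30-day death)
    imv_fraction: dict = field(default_factory=lambda: dict(REFERENCE_COHORT["imv_fraction"]))
    crrt_fraction: dict = field(default_factory=lambda: dict(REFERENCE_COHORT["crrt_fraction"]))
    cvc_fraction: dict = field(default_factory=lambda: {"secondary": 0.5, "tertiary": 0.7})
    readmission_prob: float = 0.06
    readmission_gap_lognormal: tuple[float, float] = (math.log(30.0), 0.8)  # hours
    transfer_prob: float = 0.03
    # prescribing model
    class_weights: dict = field(default_factory=lambda: {k: dict(v) for k, v in _CLASS_WEIGHTS.items()})
    empiric_start_prob: dict = field(default_factory=lambda: {"secondary": 0.54, "tertiary": 0.64})
    empiric_los_coupling: float = 0.5   # day-0 start prob scales with (LOS/1.4 d)^coupling
    daily_class_hazard: dict = field(default_factory=lambda: {"secondary": 0.10, "tertiary": 0.13})
    extra_empiric_classes: tuple[int, float] = (2, 0.24)  # Binomial(n, p) added on day 0
    course_extra_days_mean: float = 6.0  # duration = 1 + Poisson(mean); discharge truncates
    clinic_intensity: dict = field(default_factory=lambda: dict(_CLINIC_INTENSITY))
    prescribing_intensity: dict = field(default_factory=lambda: {"secondary": 1.0, "tertiary": 1.0})
    dose_jitter_sd_hours: float = 0.3
    missing_atc_fraction: float = 0.006
    # case-mix overlay: (start, end, peak daily count, intensity multiplier)
    covid_waves: tuple = ((date(2020, 4, 3), date(2020, 6, 14), 12, 0.8),
                         (date(2021, 2, 8), date(2021, 5, 28), 15, 0.8))
    # dispensing model: shelf supply = administered mass x drug factor
    dispensing_factor: float = 1.25
    dispensing_noise_sd: float = 0.1
    dispensing_overrides: dict = field(default_factory=lambda: {"J01CF02": 3.0})

    def __post_init__(self) -> None:
        if not self.clinic_mix:
            self.clinic_mix = {
                level: {c: n / sum(mix.values()) for c, n in mix.items()}
                for level, mix in REFERENCE_COHORT["clinic_mix"].items()
            }
        if not self.los_lognormal:
            self.los_lognormal = {
                key: lognormal_from_median_iqr(*target)
                for key, target in REFERENCE_COHORT["los_median_iqr"].items()
            }
        if not self.saps3_normal:
            self.saps3_normal = {
                level: (float(m), (hi - lo) / (2 * _Z_IQR))
                for level, (m, lo, hi) in REFERENCE_COHORT["saps3_median_iqr"].items()
            }
        self.validate()

    def validate(self) -> None:
        problems = []
        for name in ("tertiary_fraction", "female_fraction", "minors_fraction",
                     "readmission_prob", "transfer_prob", "missing_atc_fraction",
                     "icu_death_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                problems.append(f"{name}={value} outside [0, 1]")
        for level, mix in self.clinic_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                problems.append(f"clinic_mix[{level}] does not sum to 1")
        if self.n_patients < 1:
            problems.append("n_patients must be >= 1")
        if self.start_date > self.end_date:
            problems.append("start_date after end_date")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))


def lognormal_from_median_iqr(median: float, q25: float, q75: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and quartiles."""
    if not 0 < q25 <= median <= q75:
        raise ValueError("need 0 < q25 <= median <= q75")
    sigma = math.log(q75 / q25) / (2 * _Z_IQR) if q75 > q25 else 0.0
    return math.log(median), sigma


def emr_center_from_median(saps3_median: float, emr_median: float, slope: float) -> float:
    """Centre of the logistic severity→EMR transform hitting the target median."""
    return saps3_median - math.log(emr_median / (1 - emr_median)) / slope


def calibrate_to_paper(targets: dict) -> GeneratorConfig:
    """Build a configuration whose large-sample output matches the targets.

    ``targets`` uses the same keys as :data:`REFERENCE_COHORT` (any subset;
    unspecified aspects keep their defaults).  Median/IQR targets invert to
    log-normal or normal parameters in closed form; mixes normalise to
    probabilities; the EMR transform centre solves the logistic equation for
    the target median.
    """
    config = GeneratorConfig()
    if "n_patients" in targets:
        config.n_patients = int(targets["n_patients"])
    if "period" in targets:
        start, end = targets["period"]
        config.start_date = date.fromisoformat(start) if isinstance(start, str) else start
        config.end_date = date.fromisoformat(end) if isinstance(end, str) else end
    if "care_level_mix" in targets:
        config.tertiary_fraction = (targets["care_level_mix"]["tertiary"]
                                    / sum(targets["care_level_mix"].values()))
    if "female_fraction" in targets:
        config.female_fraction = float(targets["female_fraction"])
    if "minors_fraction" in targets:
        config.minors_fraction = float(targets["minors_fraction"])
    if "age_median_iqr" in targets:
        median, q25, q75 = targets["age_median_iqr"]
        config.age_split_normal = (float(median), (median - q25) / _Z_IQR,
                                   (q75 - median) / _Z_IQR)
    if "clinic_mix" in targets:
        config.clinic_mix = {
            level: {c: n / sum(mix.values()) for c, n in mix.items()}
            for level, mix in targets["clinic_mix"].items()
        }
    if "los_median_iqr" in targets:
        config.los_lognormal = {
            tuple(key): lognormal_from_median_iqr(*value)
            for key, value in targets["los_median_iqr"].items()
        }
    if "saps3_median_iqr" in targets:
        config.saps3_normal = {
            level: (float(m), (hi - lo) / (2 * _Z_IQR))
            for level, (m, lo, hi) in targets["saps3_median_iqr"].items()
        }
    if "emr_median" in targets:
        config.emr_center = {
            level: emr_center_from_median(config.saps3_normal[level][0],
                                          float(median), config.emr_slope)
            for level, median in targets["emr_median"].items()
        }
    if "imv_fraction" in targets:
        config.imv_fraction = dict(targets["imv_fraction"])
    if "crrt_fraction" in targets:
        config.crrt_fraction = dict(targets["crrt_fraction"])
    if "prescribing_intensity" in targets:
        config.prescribing_intensity = dict(targets["prescribing_intensity"])
    config.validate()
    return config


def default_config(seed: int = 0, n_patients: int | None = None) -> GeneratorConfig:
    """The reference-cohort configuration (optionally rescaled)."""
    config = calibrate_to_paper(REFERENCE_COHORT)
    config.seed = seed
    if n_patients is not None:
        config.n_patients = n_patients
    return config


# --- independent DDD index (generator-side parse; no registry import) -------

def _ddd_index() -> dict[str, dict]:
    index: dict[str, dict] = {}
    source = resources.files("icuamc.data").joinpath("atc_ddd.tsv")
    with resources.as_file(source) as path, open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter="\t")
        next(reader)
        for row in reader:
            if not row or not row[0].strip():
                continue
            row = (row + [""] * 7)[:7]
            code, _name, label, group, value, unit, route = (c.strip() for c in row)
            entry = index.setdefault(code, {"class": label, "group": group, "ddd": {}})
            if value:
                entry["ddd"][route or "*"] = (float(value), unit)
    return index


def _ddd_of(index: dict, code: str, route: str, amount: float, unit: str) -> float | None:
    entry = index.get(code)
    if entry is None:
        return None
    ddd = entry["ddd"].get(route) or entry["ddd"].get("*")
    if ddd is None:
        return None
    value, ddd_unit = ddd
    in_grams = {"mg": 0.001, "g": 1.0}
    if unit == ddd_unit:
        return amount / value
    if unit in in_grams and ddd_unit in in_grams:
        return amount * in_grams[unit] / (value * in_grams[ddd_unit])
    return None


# --- generation --------------------------------------------------------------

@dataclass
class SyntheticDataset:
    admissions: "object"       # pandas DataFrame in the ingest schema
    administrations: "object"
    dispensing: "object"
    truth: dict


def _split_normal(rng, mode: float, sd_lo: float, sd_hi: float) -> float:
    z = abs(rng.standard_normal())
    side_hi = rng.random() < sd_hi / (sd_lo + sd_hi)
    return mode + z * sd_hi if side_hi else mode - z * sd_lo


def _wave_state(config: GeneratorConfig, day: date) -> tuple[int, float]:
    """(overlay count, prescribing multiplier) for one calendar day."""
    for start, end, peak, multiplier in config.covid_waves:
        if start <= day <= end:
            span = (end - start).days
            phase = (day - start).days / span if span else 0.5
            count = int(round(peak * math.sin(math.pi * phase)))
            return count, multiplier
    return 0, 1.0


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw the full synthetic cohort and enumerate its ground truth."""
    import pandas as pd  # deferred: keeps module import light for config use

    rng = np.random.default_rng(config.seed)
    index = _ddd_index()
    levels = ("secondary", "tertiary")
    period_days = (config.end_date - config.start_date).days + 1

    admission_rows: list[dict] = []
    dose_rows: list[dict] = []
    truth_admissions: dict[str, dict] = {}
    truth_episodes: dict[str, dict] = {}
    n_missing_atc = 0
    adm_counter = 0
    dose_counter = 0

    class_names = {level: sorted(config.class_weights[level]) for level in levels}
    class_probs = {}
    for level in levels:
        weights = np.array([config.class_weights[level][c] for c in class_names[level]])
        class_probs[level] = weights / weights.sum()

    for patient_idx in range(config.n_patients):
        patient_id = f"P{patient_idx + 1:05d}"
        care_level = "tertiary" if rng.random() < config.tertiary_fraction else "secondary"
        if rng.random() < config.minors_fraction:
            age = int(rng.integers(1, 18))
        else:
            age = int(round(np.clip(_split_normal(rng, *config.age_split_normal), 18, 100)))
        sex = "female" if rng.random() < config.female_fraction else "male"
        mix = config.clinic_mix[care_level]
        clinics = sorted(mix)
        clinic = str(rng.choice(clinics, p=np.array([mix[c] for c in clinics])))

        saps_mean, saps_sd = config.saps3_normal[care_level]
        saps3 = int(np.clip(round(rng.normal(saps_mean, saps_sd)), 15, 120))
        emr = round(1.0 / (1.0 + math.exp(-config.emr_slope
                                          * (saps3 - config.emr_center[care_level]))), 4)
        died_30d = bool(rng.random() < emr)
        died_icu = bool(died_30d and rng.random() < config.icu_death_fraction)

        # admission chain: index admission, then possible transfer/readmission
        admit = (datetime.combine(
            config.start_date + timedelta(days=int(rng.integers(0, period_days))),
            datetime.min.time(),
        ) + timedelta(hours=float(rng.uniform(0, 24)))).replace(microsecond=0)
        chain: list[tuple[datetime, datetime, str, str]] = []  # admit, discharge, level, clinic
        current_level = care_level
        while True:
            mu, sigma = config.los_lognormal.get(
                (current_level, clinic),
                config.los_lognormal[(current_level, "other")]
                if (current_level, "other") in config.los_lognormal
                else (0.0, 1.0),
            )
            los_days = float(np.clip(rng.lognormal(mu, sigma), 2.0 / 24.0, 60.0))
            discharge = (admit + timedelta(days=los_days)).replace(microsecond=0)
            chain.append((admit, discharge, current_level, clinic))
            if len(chain) >= 3:
                break
            if rng.random() < config.transfer_prob:
                current_level = "tertiary" if current_level == "secondary" else "secondary"
                admit = (discharge
                         + timedelta(hours=float(rng.uniform(0.5, 6.0)))).replace(microsecond=0)
            elif rng.random() < config.readmission_prob:
                gap_mu, gap_sigma = config.readmission_gap_lognormal
                admit = (discharge + timedelta(
                    hours=float(rng.lognormal(gap_mu, gap_sigma)))).replace(microsecond=0)
            else:
                break

        episode_members: list[list[str]] = []
        episode_classes: list[set[str]] = []
        episode_level: list[str] = []
        episode_los: list[float] = []
        prev_discharge: datetime | None = None

        for admit_ts, discharge_ts, level, adm_clinic in chain:
            adm_counter += 1
            admission_id = f"A{adm_counter:06d}"
            los_days = (discharge_ts - admit_ts).total_seconds() / 86400.0

            imv = rng.random() < config.imv_fraction[level]
            imv_hours = (round(float(np.clip(rng.lognormal(math.log(40.0), 1.2),
                                             1.0, los_days * 24.0)), 1) if imv else None)
            crrt = rng.random() < config.crrt_fraction[level]
            crrt_hours = (round(float(np.clip(rng.lognormal(math.log(80.0), 0.8),
                                              2.0, los_days * 24.0)), 1) if crrt else None)
            cvc = rng.random() < config.cvc_fraction[level]
            cvc_hours = (round(float(np.clip(rng.lognormal(math.log(75.0), 1.0),
                                             2.0, los_days * 24.0)), 1) if cvc else None)
            unit_id = ("ICU-T" if level == "tertiary"
                       else ("ICU-S1" if rng.random() < 0.6 else "ICU-S2"))
            last_of_chain = (admit_ts, discharge_ts) == (chain[-1][0], chain[-1][1])
            admission_rows.append({
                "admission_id": admission_id, "patient_id": patient_id,
                "unit_id": unit_id, "care_level": level,
                "admit_ts": admit_ts,
                "discharge_ts": discharge_ts,
                "age_years": age, "sex": sex, "referring_clinic": adm_clinic,
                "saps3_score": saps3, "saps3_emr": emr,
                "imv_hours": imv_hours, "crrt_hours": crrt_hours, "cvc_hours": cvc_hours,
                "died_in_icu": died_icu and last_of_chain,
                "died_within_30d": died_30d,
            })

            # prescribing: day-indexed class courses, doses at nursing rounds
            agent_days: set[tuple[date, str]] = set()
            ddd_total = 0.0
            classes_seen: set[str] = set()
            if age >= 18:
                names = class_names[level]
                probs = class_probs[level]
                intensity = (config.clinic_intensity.get(adm_clinic, 1.0)
                             * config.prescribing_intensity[level])
                active_until: dict[str, int] = {}
                first_date = admit_ts.date()
                n_dates = (discharge_ts.date() - first_date).days + 1
                for day_idx in range(n_dates):
                    day = first_date + timedelta(days=day_idx)
                    _count, wave_mult = _wave_state(config, day)
                    starts: list[str] = []
                    if day_idx == 0:
                        los_factor = (los_days / 1.4) ** config.empiric_los_coupling
                        p0 = min(1.0, config.empiric_start_prob[level] * intensity
                                 * wave_mult * los_factor)
                        if rng.random() < p0:
                            n_extra, p_extra = config.extra_empiric_classes
                            k = 1 + int(rng.binomial(n_extra, p_extra))
                            starts.extend(rng.choice(names, size=k, replace=False, p=probs))
                    else:
                        hazard = min(1.0, config.daily_class_hazard[level] * intensity * wave_mult)
                        if rng.random() < hazard:
                            starts.append(str(rng.choice(names, p=probs)))
                    for label in starts:
                        if active_until.get(label, -1) >= day_idx:
                            continue
                        duration = 1 + int(rng.poisson(config.course_extra_days_mean))
                        active_until[label] = day_idx + duration - 1
                    for label, until in active_until.items():
                        if until < day_idx:
                            continue
                        drugs = _DRUGS[label]
                        weights = np.array([d[5] for d in drugs])
                        pick = drugs[int(rng.choice(len(drugs), p=weights / weights.sum()))]
                        atc, route, per_day, amount, unit, _w = pick
                        round_hours = [6.0, 12.0, 18.0, 23.83][:per_day]
                        for hour in round_hours:
                            ts = (datetime.combine(day, datetime.min.time())
                                  + timedelta(hours=hour + float(rng.normal(0, config.dose_jitter_sd_hours))))
                            if ts < admit_ts or ts > discharge_ts:
                                continue
                            ts = ts.replace(microsecond=0)
                            dose_counter += 1
                            missing = rng.random() < config.missing_atc_fraction
                            dose_rows.append({
                                "record_id": f"D{dose_counter:07d}",
                                "admission_id": admission_id,
                                "timestamp": ts,
                                "atc_code": "" if missing else atc,
                                "amount": amount, "amount_unit": unit, "route": route,
                            })
                            if missing:
                                n_missing_atc += 1
                                continue
                            agent_days.add((ts.date(), atc))
                            classes_seen.add(label)
                            ddd = _ddd_of(index, atc, route, amount, unit)
                            if ddd is not None:
                                ddd_total += ddd

            truth_admissions[admission_id] = {
                "patient_id": patient_id, "care_level": level, "unit_id": unit_id,
                "referring_clinic": adm_clinic, "age_years": age,
                "dot": len(agent_days),
                "lot": len({d for d, _ in agent_days}),
                "ddd": round(ddd_total, 6),
                "classes": sorted(classes_seen),
                "patient_days": round(los_days, 6),
            }

            # generator-side episode grouping (strict 48 h gap rule)
            if (age >= 18 and prev_discharge is not None
                    and (admit_ts - prev_discharge).total_seconds() / 3600.0 < 48.0):
                episode_members[-1].append(admission_id)
                episode_classes[-1] |= classes_seen
                episode_los[-1] += los_days
            elif age >= 18:
                episode_members.append([admission_id])
                episode_classes.append(set(classes_seen))
                episode_level.append(level)
                episode_los.append(los_days)
            prev_discharge = discharge_ts

        for members, classes, level, los in zip(episode_members, episode_classes,
                                                episode_level, episode_los):
            n_classes = len(classes)
            level_name = ("none", "one", "two", "three", "more_than_three")[min(n_classes, 4)]
            truth_episodes[f"T{len(truth_episodes) + 1:06d}"] = {
                "admission_ids": members,
                "care_level": level,
                "n_classes": n_classes,
                "level": level_name,
                "classes": sorted(classes),
                "los_days": round(los, 6),
            }

    admissions = pd.DataFrame(admission_rows).sort_values(
        ["admit_ts", "admission_id"]).reset_index(drop=True)
    administrations = pd.DataFrame(
        dose_rows,
        columns=["record_id", "admission_id", "timestamp", "atc_code",
                 "amount", "amount_unit", "route"],
    )
    if not administrations.empty:
        administrations = administrations.sort_values(
            ["timestamp", "record_id"]).reset_index(drop=True)

    dispensing = _dispense(config, administrations, rng)
    overlay = {}
    day = config.start_date
    while day <= config.end_date:
        count, _mult = _wave_state(config, day)
        if count:
            overlay[day.isoformat()] = count
        day += timedelta(days=1)

    adult = admissions[admissions["age_years"] >= 18]
    totals: dict[str, dict] = {}
    for scope, mask in (("all", adult.index),
                        ("secondary", adult.index[adult["care_level"] == "secondary"]),
                        ("tertiary", adult.index[adult["care_level"] == "tertiary"])):
        ids = adult.loc[mask, "admission_id"]
        rows = [truth_admissions[i] for i in ids]
        totals[scope] = {
            "dot": sum(r["dot"] for r in rows),
            "lot": sum(r["lot"] for r in rows),
            "ddd": round(sum(r["ddd"] for r in rows), 6),
            "patient_days": round(sum(r["patient_days"] for r in rows), 6),
            "n_admissions": len(rows),
            "n_amu_admissions": sum(1 for r in rows if r["dot"] > 0),
        }

    truth = {
        "config": config_to_dict(config),
        "admissions": truth_admissions,
        "episodes": truth_episodes,
        "totals": totals,
        "missing_atc_doses": n_missing_atc,
        "covid_overlay": overlay,
    }
    return SyntheticDataset(admissions, administrations, dispensing, truth)


def _dispense(config: GeneratorConfig, administrations, rng):
    """Quarterly shelf supply per unit and drug, inflated vs administration."""
    import pandas as pd

    columns = ["unit_id", "period_start", "period_end", "atc_code", "amount", "amount_unit"]
    if administrations.empty:
        return pd.DataFrame(columns=columns)
    frame = administrations[administrations["atc_code"] != ""].copy()
    frame["quarter"] = frame["timestamp"].map(lambda t: (t.year, (t.month - 1) // 3))
    # dispensing is unit-level; infer unit from the admission id prefix is not
    # possible here, so supply is pooled per care-level shelf via drug totals
    grouped = frame.groupby(["quarter", "atc_code", "amount_unit"], as_index=False)["amount"].sum()
    rows = []
    for row in grouped.itertuples(index=False):
        year, quarter = row.quarter
        factor = config.dispensing_overrides.get(
            row.atc_code, config.dispensing_factor
        ) * float(max(0.5, 1.0 + rng.normal(0, config.dispensing_noise_sd)))
        start = date(year, 3 * quarter + 1, 1)
        end_month = 3 * quarter + 3
        end = (date(year + 1, 1, 1) if end_month == 12
               else date(year, end_month + 1, 1)) - timedelta(days=1)
        rows.append({
            "unit_id": "ALL", "period_start": start.isoformat(),
            "period_end": end.isoformat(), "atc_code": row.atc_code,
            "amount": round(row.amount * factor, 3), "amount_unit": row.amount_unit,
        })
    rows.sort(key=lambda r: (r["period_start"], r["atc_code"]))
    return pd.DataFrame(rows, columns=columns)


def _listify(value):
    if isinstance(value, tuple):
        return [_listify(v) for v in value]
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_listify(v) for v in value]
    return value


def config_to_dict(config: GeneratorConfig) -> dict:
    raw = asdict(config)
    raw["start_date"] = config.start_date.isoformat()
    raw["end_date"] = config.end_date.isoformat()
    raw["los_lognormal"] = {f"{level}|{clinic}": list(value)
                            for (level, clinic), value in config.los_lognormal.items()}
    raw["covid_waves"] = [[s.isoformat(), e.isoformat(), peak, mult]
                          for s, e, peak, mult in config.covid_waves]
    return _listify(raw)


def config_from_dict(raw: dict) -> GeneratorConfig:
    raw = dict(raw)
    raw["start_date"] = date.fromisoformat(raw["start_date"])
    raw["end_date"] = date.fromisoformat(raw["end_date"])
    raw["los_lognormal"] = {tuple(key.split("|")): tuple(value)
                            for key, value in raw["los_lognormal"].items()}
    raw["covid_waves"] = tuple((date.fromisoformat(s), date.fromisoformat(e), peak, mult)
                               for s, e, peak, mult in raw["covid_waves"])
    for name in ("age_split_normal", "readmission_gap_lognormal", "extra_empiric_classes"):
        raw[name] = tuple(raw[name])
    raw["saps3_normal"] = {k: tuple(v) for k, v in raw["saps3_normal"].items()}
    return GeneratorConfig(**raw)


def load_config(path: str | Path) -> GeneratorConfig:
    with open(path, encoding="utf-8") as handle:
        return config_from_dict(yaml.safe_load(handle))


def save_config(config: GeneratorConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(config_to_dict(config), handle, sort_keys=True)


def generate(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write admissions.csv, administrations.csv, dispensing.csv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset = generate_dataset(config)
    paths = {
        "admissions": outdir / "admissions.csv",
        "administrations": outdir / "administrations.csv",
        "dispensing": outdir / "dispensing.csv",
        "truth": outdir / "truth.json",
    }
    admissions = dataset.admissions.copy()
    for column in ("admit_ts", "discharge_ts"):
        admissions[column] = admissions[column].map(lambda t: t.isoformat())
    for column in ("imv_hours", "crrt_hours", "cvc_hours"):
        admissions[column] = admissions[column].map(lambda v: "" if v is None else v)
    for column in ("died_in_icu", "died_within_30d"):
        admissions[column] = admissions[column].map(lambda v: str(bool(v)).lower())
    admissions.to_csv(paths["admissions"], index=False)
    administrations = dataset.administrations.copy()
    if not administrations.empty:
        administrations["timestamp"] = administrations["timestamp"].map(lambda t: t.isoformat())
    administrations.to_csv(paths["administrations"], index=False)
    dataset.dispensing.to_csv(paths["dispensing"], index=False)
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        json.dump(dataset.truth, handle, indent=1, sort_keys=True)
    return paths
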