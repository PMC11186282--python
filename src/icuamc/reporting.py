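"""Standard surveillance reports.

Compiles the population table, referral-clinic table, class-by-care-level
consumption, per-clinic consumption with bootstrap confidence intervals, the
three-metric comparison (DOT vs administered DDD vs pharmacy-dispensed DDD),
and a data-quality summary.  Every printed rate is derived from the same
stratum totals the metrics module computed — reports never re-derive.

Printed precision follows surveillance convention: rates per 1000 patient-days
round half-up to integers, percentages to one decimal in the population table
and to integers in exposure tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ingest import DispensingRecord
from .issues import IssueLog
from .metrics import rate_per_1000_pd
from .outcomes import mortality_summary
from .registry import AtcRegistry

DIVERGENCE_THRESHOLD = 1.5
BOOTSTRAP_REPS = 1000


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed."""
    quantum = Decimal(1).scaleb(-ndigits)
    result = float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))
    return result if ndigits > 0 else int(result) if ndigits == 0 else result


def percent(numerator: float, denominator: float, ndigits: int = 0) -> float | None:
    """Half-up rounded percentage; None for an empty denominator."""
    if denominator == 0:
        return None
    return round_half_up(numerator / denominator * 100.0, ndigits)


def per_mille(numerator: float, denominator: float, ndigits: int = 0) -> float | None:
    if denominator == 0:
        return None
    return round_half_up(numerator / denominator * 1000.0, ndigits)


@dataclass
class ReportBundle:
    population_table: pd.DataFrame
    clinic_table: pd.DataFrame
    class_consumption: pd.DataFrame
    clinic_consumption: pd.DataFrame
    metric_comparison: pd.DataFrame
    quality_summary: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "population": self.population_table,
            "clinics": self.clinic_table,
            "class_consumption": self.class_consumption,
            "clinic_consumption": self.clinic_consumption,
            "metric_comparison": self.metric_comparison,
            "quality": self.quality_summary,
        }


def _fmt_median_iqr(values: list[float], ndigits: int = 1) -> str:
    if not values:
        return ""
    q25, med, q75 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    fmt = f"{{:.{ndigits}f}}"
    return f"{fmt.format(med)} ({fmt.format(q25)}-{fmt.format(q75)})"


def population_table(episodes) -> pd.DataFrame:
    """Patient characteristics by ICU care level (admission denominators).

    Rows are characteristics, columns the overall cohort and each care
    level.  Medians print with IQR; percentages with one decimal.
    """
    groups = {"all": list(episodes)}
    for ep in episodes:
        groups.setdefault(ep.care_level_of_record, []).append(ep)
    summary = mortality_summary(episodes)
    columns = ["all"] + sorted(k for k in groups if k != "all")
    rows: dict[str, dict[str, str]] = {}

    def put(characteristic: str, column: str, value) -> None:
        rows.setdefault(characteristic, {})[column] = "" if value is None else str(value)

    for col in columns:
        members = groups[col]
        admissions = [a for ep in members for a in ep.admissions]
        n = len(admissions)
        put("admissions_n", col, n)
        put("episodes_n", col, len(members))
        females = sum(1 for a in admissions if a.sex == "female")
        put("female_n_pct", col, f"{females} ({percent(females, n, 1)})" if n else "")
        put("median_age_iqr_yr", col, _fmt_median_iqr([a.age_years for a in admissions], 0))
        put("admissions_los_gt_48h_n", col,
            sum(1 for a in admissions if a.los_days > 2.0))
        put("patient_days_n", col, round_half_up(sum(a.los_days for a in admissions)))
        put("median_los_iqr_days", col, _fmt_median_iqr([a.los_days for a in admissions]))
        imv = [a.imv_hours for a in admissions if a.imv_hours]
        put("admissions_with_imv_n_pct", col,
            f"{len(imv)} ({percent(len(imv), n, 1)})" if n else "")
        put("imv_hours_median_iqr", col, _fmt_median_iqr(imv, 0))
        crrt = [a.crrt_hours for a in admissions if a.crrt_hours]
        put("admissions_with_crrt_n_pct", col,
            f"{len(crrt)} ({percent(len(crrt), n, 1)})" if n else "")
        put("crrt_hours_median_iqr", col, _fmt_median_iqr(crrt, 0))
        cvc = [a.cvc_hours for a in admissions if a.cvc_hours]
        put("cvc_hours_median_iqr", col, _fmt_median_iqr(cvc, 0))
        put("saps3_median_iqr", col,
            _fmt_median_iqr([a.saps3_score for a in admissions if a.saps3_score is not None], 0))
        put("saps3_emr_median_iqr", col,
            _fmt_median_iqr([a.saps3_emr for a in admissions if a.saps3_emr is not None], 2))
        stats = summary[col if col in summary else "all"]
        for key, label in (("icu_mortality_admission", "icu_mortality_pct"),
                           ("mortality_30d_admission", "mortality_30d_pct"),
                           ("icu_mortality_episode", "icu_mortality_episode_pct"),
                           ("mortality_30d_episode", "mortality_30d_episode_pct")):
            value = stats[key]
            put(label, col, "" if value is None else round_half_up(100 * value, 1))
    table = pd.DataFrame(
        [{"characteristic": name, **values} for name, values in rows.items()],
        columns=["characteristic"] + columns,
    )
    return table


def clinic_table(episodes) -> pd.DataFrame:
    """Admissions, patient-days and LOS by care level and referring clinic."""
    admissions = [a for ep in episodes for a in ep.admissions]
    rows = []
    keys = sorted({(a.care_level, a.referring_clinic) for a in admissions})
    for care_level, clinic in keys:
        members = [a for a in admissions
                   if a.care_level == care_level and a.referring_clinic == clinic]
        women = [a for a in members if a.sex == "female"]
        rows.append({
            "care_level": care_level,
            "referring_clinic": clinic,
            "admissions_n": len(members),
            "admissions_women_n": len(women),
            "patient_days_n": round_half_up(sum(a.los_days for a in members)),
            "patient_days_women_n": round_half_up(sum(a.los_days for a in women)),
            "median_los_iqr_days": _fmt_median_iqr([a.los_days for a in members]),
        })
    return pd.DataFrame(rows, columns=[
        "care_level", "referring_clinic", "admissions_n", "admissions_women_n",
        "patient_days_n", "patient_days_women_n", "median_los_iqr_days",
    ])


def class_consumption(class_frame: pd.DataFrame, adm_frame: pd.DataFrame) -> pd.DataFrame:
    """DOT and administered-DDD rates per drug class and care level."""
    if class_frame.empty:
        return pd.DataFrame(columns=["care_level", "class_label", "dot",
                                     "ddd_administered", "dot_rate", "ddd_rate"])
    pd_by_level = adm_frame.groupby("care_level")["patient_days"].sum().to_dict()
    grouped = (class_frame.groupby(["care_level", "class_label"], as_index=False)
               [["dot", "ddd_administered"]].sum())
    grouped["dot_rate"] = [
        None if rate is None else round_half_up(rate)
        for rate in (rate_per_1000_pd(row.dot, pd_by_level.get(row.care_level, 0.0))
                     for row in grouped.itertuples())
    ]
    grouped["ddd_rate"] = [
        None if rate is None else round_half_up(rate)
        for rate in (rate_per_1000_pd(row.ddd_administered,
                                      pd_by_level.get(row.care_level, 0.0))
                     for row in grouped.itertuples())
    ]
    return grouped.sort_values(["care_level", "dot"], ascending=[True, False]).reset_index(drop=True)


def clinic_consumption(
    adm_frame: pd.DataFrame,
    n_boot: int = BOOTSTRAP_REPS,
    seed: int = 0,
) -> pd.DataFrame:
    """DOT rate per referring clinic with a bootstrap 95% CI.

    The CI resamples admissions within the clinic with replacement
    (percentile interval, seeded, default 1000 resamples); a clinic with no
    patient-days is omitted with a note row.
    """
    rng = np.random.default_rng(seed)
    rows = []
    keys = (adm_frame[["care_level", "referring_clinic"]].drop_duplicates()
            .sort_values(["care_level", "referring_clinic"]))
    for care_level, clinic in keys.itertuples(index=False):
        members = adm_frame[(adm_frame["care_level"] == care_level)
                            & (adm_frame["referring_clinic"] == clinic)]
        dots = members["dot"].to_numpy(dtype=float)
        pdays = members["patient_days"].to_numpy(dtype=float)
        total_pd = float(pdays.sum())
        if total_pd == 0:
            rows.append({"care_level": care_level, "referring_clinic": clinic,
                         "n_admissions": len(members), "dot": int(dots.sum()),
                         "patient_days": 0.0, "dot_rate": None,
                         "ci_low": None, "ci_high": None,
                         "note": "omitted: no patient-days"})
            continue
        rate = rate_per_1000_pd(float(dots.sum()), total_pd)
        n = len(members)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_pd = pdays[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boot_rates = np.where(boot_pd > 0, dots[idx].sum(axis=1) / boot_pd * 1000.0, np.nan)
        lo, hi = np.nanpercentile(boot_rates, [2.5, 97.5])
        rows.append({"care_level": care_level, "referring_clinic": clinic,
                     "n_admissions": n, "dot": int(dots.sum()),
                     "patient_days": total_pd,
                     "dot_rate": round_half_up(rate),
                     "ci_low": round_half_up(float(lo)),
                     "ci_high": round_half_up(float(hi)), "note": ""})
    return pd.DataFrame(rows, columns=["care_level", "referring_clinic", "n_admissions",
                                       "dot", "patient_days", "dot_rate", "ci_low",
                                       "ci_high", "note"])


def metric_comparison(
    class_frame: pd.DataFrame,
    dispensing: list[DispensingRecord],
    registry: AtcRegistry,
    patient_days: float,
    minors_count: int = 0,
    minors_patient_days: float = 0.0,
    threshold: float = DIVERGENCE_THRESHOLD,
) -> pd.DataFrame:
    """Per drug and class: DOT rate, administered-DDD rate, dispensed-DDD rate.

    Dispensing covers the whole medicine shelf, which may also have served
    under-18 admissions; when their patient-days are supplied the dispensed
    denominator includes them, and the minor-admission count is echoed.  A
    divergence flag marks drugs whose dispensed/administered DDD ratio
    exceeds ``threshold`` (or that were dispensed but never administered).
    """
    dispensed_ddd: dict[str, float] = {}
    for record in dispensing:
        # shelf stock on an ICU is parenteral: convert with the IV-route DDD
        value = registry.ddd_equivalents(record.atc_code, "IV", record.amount,
                                         record.amount_unit)
        if value is not None:
            dispensed_ddd[record.atc_code] = dispensed_ddd.get(record.atc_code, 0.0) + value
    have_dispensing = bool(dispensing)
    dispensed_pd = patient_days + (minors_patient_days if have_dispensing else 0.0)

    administered = (class_frame.groupby(["class_label", "atc_code", "substance_name"],
                                        as_index=False)[["dot", "ddd_administered"]].sum()
                    if not class_frame.empty else
                    pd.DataFrame(columns=["class_label", "atc_code", "substance_name",
                                          "dot", "ddd_administered"]))
    known = set(administered["atc_code"])
    extra = []
    for code in sorted(set(dispensed_ddd) - known):
        entry = registry.lookup(code)
        if entry is None:
            continue
        extra.append({"class_label": entry.class_label, "atc_code": code,
                      "substance_name": entry.substance_name, "dot": 0,
                      "ddd_administered": 0.0})
    if extra:
        administered = pd.concat([administered, pd.DataFrame(extra)], ignore_index=True)

    rows = []
    for row in administered.itertuples(index=False):
        dispensed = dispensed_ddd.get(row.atc_code)
        ratio = None
        if have_dispensing and dispensed is not None:
            ratio = (dispensed / row.ddd_administered) if row.ddd_administered > 0 else np.inf
        flagged = bool(ratio is not None and ratio > threshold)
        rows.append({
            "class_label": row.class_label,
            "atc_code": row.atc_code,
            "substance_name": row.substance_name,
            "dot": int(row.dot),
            "dot_rate": (round_half_up(rate_per_1000_pd(row.dot, patient_days))
                         if patient_days else None),
            "ddd_administered_rate": (round_half_up(rate_per_1000_pd(row.ddd_administered,
                                                                     patient_days))
                                      if patient_days else None),
            "ddd_dispensed_rate": (round_half_up(rate_per_1000_pd(dispensed, dispensed_pd))
                                   if have_dispensing and dispensed is not None and dispensed_pd
                                   else None),
            "dispensed_administered_ratio": (None if ratio is None or not np.isfinite(ratio)
                                             else round(ratio, 2)),
            "divergence_flag": flagged,
            "minors_admissions_accounted": minors_count if have_dispensing else 0,
        })
    return pd.DataFrame(rows, columns=[
        "class_label", "atc_code", "substance_name", "dot", "dot_rate",
        "ddd_administered_rate", "ddd_dispensed_rate", "dispensed_administered_ratio",
        "divergence_flag", "minors_admissions_accounted",
    ]).sort_values(["class_label", "atc_code"]).reset_index(drop=True)


def quality_summary(
    logs: dict[str, IssueLog],
    n_doses: int,
    n_missing_atc: int,
    undefined_ddd_dot_share: float,
    minors_excluded: int,
) -> pd.DataFrame:
    """Counts that make the omission rules auditable."""
    rows = []
    for source, log in logs.items():
        rows.append({"item": f"{source}_rejects", "value": log.count("reject")})
        rows.append({"item": f"{source}_warns", "value": log.count("warn")})
    rows.append({"item": "doses_total", "value": n_doses})
    rows.append({"item": "doses_missing_atc", "value": n_missing_atc})
    rows.append({"item": "doses_missing_atc_per_mille",
                 "value": per_mille(n_missing_atc, n_doses) if n_doses else None})
    rows.append({"item": "undefined_ddd_dot_share_pct",
                 "value": round_half_up(100 * undefined_ddd_dot_share, 1)})
    rows.append({"item": "minors_admissions_excluded", "value": minors_excluded})
    return pd.DataFrame(rows, columns=["item", "value"])


def render(
    bundle: ReportBundle,
    outdir: str | Path,
    fmt: str = "csv",
    provenance: str = "",
) -> list[Path]:
    """Write the bundle as deterministic CSV files (optional .xlsx mirror).

    Each CSV starts with a provenance comment line (tool version plus the
    caller's configuration hash) so a report can always be traced to the
    run that produced it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# icuamc {__version__}" + (f" {provenance}" if provenance else "")
    paths = []
    names = {"population": "population.csv", "clinics": "clinics.csv",
             "class_consumption": "class_consumption.csv",
             "clinic_consumption": "clinic_consumption.csv",
             "metric_comparison": "metric_comparison.csv", "quality": "quality.csv"}
    for key, table in bundle.tables().items():
        path = outdir / names[key]
        with open(path, "w", encoding="utf-8", newline="") as handle:
            handle.write(header + "\n")
            table.to_csv(handle, index=False)
        paths.append(path)
    if fmt == "xlsx":
        xlsx_path = outdir / "report.xlsx"
        with pd.ExcelWriter(xlsx_path) as writer:
            for key, table in bundle.tables().items():
                table.to_excel(writer, sheet_name=key[:31], index=False)
        paths.append(xlsx_path)
    return paths
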