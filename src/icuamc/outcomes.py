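"""Exposure-stratified mortality against the SAPS 3 predicted rate.

The SAPS 3 estimated mortality rate (EMR) is a per-admission probability of
death predicted from the admission severity score.  Comparing it with the
observed ICU and 30-day mortality inside each antimicrobial-exposure level
shows whether heavily exposed patients die more often than their admission
severity alone would predict.  Episodes missing an EMR or a 30-day status are
omitted (no imputation) and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .episodes import Episode
from .exposure import LEVELS, ExposureCategory

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ExposureOutcomeSummary:
    """Predicted vs observed mortality for one exposure level."""

    level: str
    n: int
    mean_predicted_emr: float | None
    emr_ci_low: float | None
    emr_ci_high: float | None
    observed_icu_mortality: float | None
    observed_30d_mortality: float | None
    emr_distribution: tuple[float, ...] = ()


def _mean_ci(values: np.ndarray) -> tuple[float, float, float]:
    mean = float(values.mean())
    if len(values) > 1:
        se = float(values.std(ddof=1)) / np.sqrt(len(values))
    else:
        se = 0.0
    return mean, mean - Z_95 * se, mean + Z_95 * se


def exposure_mortality(
    episodes: list[Episode],
    exposures: dict[str, ExposureCategory],
) -> tuple[list[ExposureOutcomeSummary], int]:
    """One summary per exposure level, plus the count of omitted episodes.

    The mean EMR carries a normal-approximation 95% CI (mean ± z·SE).
    An empty level is still emitted, with n=0 and absent statistics, so the
    report always shows all five levels.
    """
    included: dict[str, list[Episode]] = {lvl: [] for lvl in LEVELS}
    n_excluded = 0
    for ep in episodes:
        if ep.saps3_emr is None or ep.died_within_30d is None:
            n_excluded += 1
            continue
        included[exposures[ep.episode_id].level].append(ep)
    summaries = []
    for lvl in LEVELS:
        members = included[lvl]
        if not members:
            summaries.append(ExposureOutcomeSummary(lvl, 0, None, None, None, None, None))
            continue
        emr = np.array([ep.saps3_emr for ep in members], dtype=float)
        mean, lo, hi = _mean_ci(emr)
        icu_known = [ep.died_in_icu for ep in members if ep.died_in_icu is not None]
        summaries.append(ExposureOutcomeSummary(
            level=lvl,
            n=len(members),
            mean_predicted_emr=mean,
            emr_ci_low=lo,
            emr_ci_high=hi,
            observed_icu_mortality=(sum(icu_known) / len(icu_known) if icu_known else None),
            observed_30d_mortality=sum(ep.died_within_30d for ep in members) / len(members),
            emr_distribution=tuple(float(v) for v in emr),
        ))
    return summaries, n_excluded


def exposure_mortality_frame(summaries: list[ExposureOutcomeSummary]) -> pd.DataFrame:
    rows = [{
        "level": s.level, "n": s.n, "mean_emr": s.mean_predicted_emr,
        "emr_ci_low": s.emr_ci_low, "emr_ci_high": s.emr_ci_high,
        "icu_mortality": s.observed_icu_mortality,
        "mortality_30d": s.observed_30d_mortality,
    } for s in summaries]
    return pd.DataFrame(rows, columns=["level", "n", "mean_emr", "emr_ci_low",
                                       "emr_ci_high", "icu_mortality", "mortality_30d"])


def _median_iqr(values: list[float]) -> tuple[float, float, float] | None:
    if not values:
        return None
    arr = np.array(values, dtype=float)
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q25), float(q75)


def mortality_summary(episodes: list[Episode]) -> dict:
    """Overall and per-care-level mortality, severity medians with IQR.

    Because it is unstated whether published denominators are admissions or
    episodes, both are computed: ``*_episode`` keys use episodes (ICU death =
    any member admission; 30-day status from the last), ``*_admission`` keys
    use member admissions directly.
    """
    out: dict[str, dict] = {}
    groups: dict[str, list[Episode]] = {"all": list(episodes)}
    for ep in episodes:
        groups.setdefault(ep.care_level_of_record, []).append(ep)
    for name, members in groups.items():
        admissions = [a for ep in members for a in ep.admissions]
        icu_ep = [ep.died_in_icu for ep in members if ep.died_in_icu is not None]
        d30_ep = [ep.died_within_30d for ep in members if ep.died_within_30d is not None]
        icu_adm = [a.died_in_icu for a in admissions if a.died_in_icu is not None]
        d30_adm = [a.died_within_30d for a in admissions if a.died_within_30d is not None]
        saps = [a.saps3_score for a in admissions if a.saps3_score is not None]
        emr = [a.saps3_emr for a in admissions if a.saps3_emr is not None]
        out[name] = {
            "n_episodes": len(members),
            "n_admissions": len(admissions),
            "icu_mortality_episode": sum(icu_ep) / len(icu_ep) if icu_ep else None,
            "mortality_30d_episode": sum(d30_ep) / len(d30_ep) if d30_ep else None,
            "icu_mortality_admission": sum(icu_adm) / len(icu_adm) if icu_adm else None,
            "mortality_30d_admission": sum(d30_adm) / len(d30_adm) if d30_adm else None,
            "median_saps3": _median_iqr([float(s) for s in saps]),
            "median_emr": _median_iqr(emr),
        }
    return out


def plot_exposure_mortality(summaries: list[ExposureOutcomeSummary], path) -> None:
    """Density panel per exposure level with mean EMR ± CI and observed rates."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(LEVELS), 1, figsize=(6, 2 * len(LEVELS)), sharex=True)
    for ax, s in zip(np.atleast_1d(axes), summaries):
        if s.n > 1:
            ax.hist(s.emr_distribution, bins=30, range=(0, 1), density=True,
                    color="#9ecae1", edgecolor="none")
            ax.errorbar([s.mean_predicted_emr], [0.5],
                        xerr=[[s.mean_predicted_emr - s.emr_ci_low],
                              [s.emr_ci_high - s.mean_predicted_emr]],
                        fmt="ko", capsize=3)
        title = f"{s.level} (N={s.n})"
        if s.observed_30d_mortality is not None:
            title += f"  30-day {100 * s.observed_30d_mortality:.1f}%"
        if s.observed_icu_mortality is not None:
            title += f"  ICU {100 * s.observed_icu_mortality:.1f}%"
        ax.set_title(title, fontsize=9)
        ax.set_yticks([])
    np.atleast_1d(axes)[-1].set_xlabel("predicted mortality (SAPS 3 EMR)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
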