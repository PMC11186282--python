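"""Antimicrobial exposure levels per episode, split by length of stay.

Exposure is graded by the number of distinct antimicrobial *drug classes*
(not agents) an episode was ever exposed to: none / one / two / three /
more-than-three.  It is evaluated at episode scope — merged readmissions share
one exposure history — and stratified by whether the ICU stay exceeded
48 hours, since longer stays carry higher infection risk and heavier use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .episodes import Episode
from .metrics import DailyTherapyDay

LEVELS = ("none", "one", "two", "three", "more_than_three")


def level_of(n_classes: int) -> str:
    """Order-preserving bucket of the class count."""
    if n_classes < 0:
        raise ValueError("n_classes must be >= 0")
    if n_classes >= 4:
        return "more_than_three"
    return LEVELS[n_classes]


@dataclass(frozen=True)
class ExposureCategory:
    level: str
    n_classes: int
    classes: frozenset[str]

    def __post_init__(self) -> None:
        if self.level != level_of(self.n_classes) or self.n_classes != len(self.classes):
            raise ValueError("inconsistent exposure category")


def classify_exposure(
    episode: Episode, days: list[DailyTherapyDay]
) -> ExposureCategory:
    """Union the drug classes over all member admissions' therapy days."""
    member_ids = set(episode.admission_ids)
    classes: set[str] = set()
    for day in days:
        if day.admission_id in member_ids:
            classes |= day.classes
    return ExposureCategory(level_of(len(classes)), len(classes), frozenset(classes))


def classify_all(
    episodes: list[Episode], days: list[DailyTherapyDay]
) -> dict[str, ExposureCategory]:
    """Classify every episode in one pass over the therapy days."""
    classes_by_adm: dict[str, set[str]] = {}
    for day in days:
        classes_by_adm.setdefault(day.admission_id, set()).update(day.classes)
    out = {}
    for ep in episodes:
        classes: set[str] = set()
        for admission_id in ep.admission_ids:
            classes |= classes_by_adm.get(admission_id, set())
        out[ep.episode_id] = ExposureCategory(level_of(len(classes)), len(classes),
                                              frozenset(classes))
    return out


def los_bucket(episode: Episode) -> str:
    return "gt_48h" if episode.los_gt_48h else "le_48h"


def exposure_table(
    episodes: list[Episode],
    exposures: dict[str, ExposureCategory],
    split_by_los: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exposure-level contingency counts and per-class exposure proportions.

    Returns ``(levels, classes)``:

    * ``levels`` — episode counts per (care level[, LOS bucket], level) with
      the within-stratum proportion; buckets partition the stratum.
    * ``classes`` — for each drug class, the share of episodes in the
      stratum ever exposed to it (shares do not sum to 1: an episode can be
      exposed to several classes).
    """
    strata: dict[tuple, list[Episode]] = {}
    for ep in episodes:
        key = (ep.care_level_of_record,) + ((los_bucket(ep),) if split_by_los else ())
        strata.setdefault(key, []).append(ep)

    key_cols = ["care_level"] + (["los_bucket"] if split_by_los else [])
    level_rows, class_rows = [], []
    for key in sorted(strata):
        members = strata[key]
        n_total = len(members)
        counts = {lvl: 0 for lvl in LEVELS}
        class_counts: dict[str, int] = {}
        for ep in members:
            cat = exposures[ep.episode_id]
            counts[cat.level] += 1
            for label in cat.classes:
                class_counts[label] = class_counts.get(label, 0) + 1
        for lvl in LEVELS:
            level_rows.append(dict(zip(key_cols, key)) | {
                "level": lvl, "n": counts[lvl], "n_stratum": n_total,
                "proportion": counts[lvl] / n_total if n_total else None,
            })
        for label in sorted(class_counts):
            class_rows.append(dict(zip(key_cols, key)) | {
                "class_label": label, "n_exposed": class_counts[label],
                "n_stratum": n_total,
                "proportion": class_counts[label] / n_total,
            })
    levels = pd.DataFrame(level_rows, columns=key_cols + ["level", "n", "n_stratum", "proportion"])
    classes = pd.DataFrame(class_rows, columns=key_cols + ["class_label", "n_exposed",
                                                           "n_stratum", "proportion"])
    return levels, classes


def exposure_frame(
    episodes: list[Episode], exposures: dict[str, ExposureCategory]
) -> pd.DataFrame:
    """Per-episode exposure export (semicolon-joined class list)."""
    rows = []
    for ep in episodes:
        cat = exposures[ep.episode_id]
        rows.append({
            "episode_id": ep.episode_id,
            "care_level": ep.care_level_of_record,
            "los_bucket": los_bucket(ep),
            "n_classes": cat.n_classes,
            "level": cat.level,
            "classes": ";".join(sorted(cat.classes)),
        })
    return pd.DataFrame(rows, columns=["episode_id", "care_level", "los_bucket",
                                       "n_classes", "level", "classes"])
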