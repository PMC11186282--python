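"""WHO ATC 5th-level classification and DDD values for surveilled drugs.

Membership in the registry defines the surveilled antimicrobial set (systemic
antibacterials and antifungals; topical ATC groups are out of scope).  A
curated reference table of ICU-relevant agents ships with the package; the
file is user-replaceable so a site can surveil a different formulary or pin a
different index year.

A drug may carry route-specific DDD values (oral vs parenteral), a single
route-independent value, or none at all — sulfamethoxazole/trimethoprim has no
defined DDD, and a mass-denominated DDD cannot absorb doses charted in million
units (MU).  Such drugs still count fully toward DOT and LOT; they are only
excluded from DDD sums, and the excluded share is reported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .ingest import ATC_PATTERN

# mass units convertible among themselves; MU (million units) is not a mass
_MASS_IN_GRAMS = {"mg": 0.001, "g": 1.0}

DEFAULT_REGISTRY_RESOURCE = "atc_ddd.tsv"


@dataclass(frozen=True)
class AtcEntry:
    """One surveilled substance (possibly route-specific DDD row)."""

    atc_code: str
    substance_name: str
    class_label: str
    group: str  # antibacterial | antifungal
    ddd_value: float | None = None
    ddd_unit: str | None = None
    ddd_route: str | None = None

    def __post_init__(self) -> None:
        if (self.ddd_value is None) != (self.ddd_unit is None):
            raise ValueError(f"{self.atc_code}: ddd_value and ddd_unit must be present together")
        if self.ddd_value is not None and self.ddd_value <= 0:
            raise ValueError(f"{self.atc_code}: ddd_value must be positive")
        if self.group not in ("antibacterial", "antifungal"):
            raise ValueError(f"{self.atc_code}: unknown group {self.group!r}")
        if not self.class_label:
            raise ValueError(f"{self.atc_code}: class_label must be non-empty")


class AtcRegistry:
    """Lookup table keyed by (ATC code, route)."""

    def __init__(self, entries: list[AtcEntry]):
        self._by_code: dict[str, list[AtcEntry]] = {}
        for entry in entries:
            if not ATC_PATTERN.match(entry.atc_code):
                raise ValueError(f"malformed ATC code in registry: {entry.atc_code!r}")
            self._by_code.setdefault(entry.atc_code, []).append(entry)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AtcRegistry":
        entries = []
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.reader(handle, delimiter="\t")
            header = next(reader)
            expected = ["atc_code", "substance_name", "class_label", "group",
                        "ddd_value", "ddd_unit", "ddd_route"]
            if [h.strip() for h in header] != expected:
                raise ValueError(f"registry header must be {expected}")
            for row in reader:
                if not row or not row[0].strip():
                    continue
                row = (row + [""] * 7)[:7]
                code, name, label, group, value, unit, route = (c.strip() for c in row)
                entries.append(AtcEntry(
                    atc_code=code,
                    substance_name=name,
                    class_label=label,
                    group=group,
                    ddd_value=float(value) if value else None,
                    ddd_unit=unit or None,
                    ddd_route=route or None,
                ))
        return cls(entries)

    @classmethod
    def bundled(cls) -> "AtcRegistry":
        """The curated reference table shipped with the package."""
        source = resources.files("icuamc.data").joinpath(DEFAULT_REGISTRY_RESOURCE)
        with resources.as_file(source) as path:
            return cls.from_tsv(path)

    def __contains__(self, atc_code: str) -> bool:
        return atc_code in self._by_code

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> list[str]:
        return sorted(self._by_code)

    def lookup(self, atc_code: str, route: str | None = None) -> AtcEntry | None:
        """Resolve a code (and optionally a route) to a registry entry.

        A route-specific row wins when the registry distinguishes routes;
        otherwise a route-independent row applies.  If only rows for *other*
        routes exist, classification fields are still returned but without a
        DDD, because a DDD denominated for another route must not be applied.
        ``None`` signals a non-surveilled or unknown code.
        """
        rows = self._by_code.get(atc_code)
        if not rows:
            return None
        if route is not None:
            for row in rows:
                if row.ddd_route == route:
                    return row
        for row in rows:
            if row.ddd_route is None:
                return row
        if route is None:
            return rows[0]
        template = rows[0]
        return AtcEntry(template.atc_code, template.substance_name,
                        template.class_label, template.group)

    def class_of(self, atc_code: str) -> str | None:
        rows = self._by_code.get(atc_code)
        return rows[0].class_label if rows else None

    def ddd_equivalents(
        self, atc_code: str, route: str | None, amount: float, amount_unit: str
    ) -> float | None:
        """Convert an administered amount to DDD equivalents.

        Returns ``None`` (undefined, never a silent zero) when the drug has
        no DDD for the route or the units are incommensurable — e.g. an
        amount charted in MU against a gram-denominated index value.
        """
        if amount < 0:
            raise ValueError("amount must be non-negative")
        entry = self.lookup(atc_code, route)
        if entry is None or entry.ddd_value is None:
            return None
        if amount_unit == entry.ddd_unit:
            return amount / entry.ddd_value
        if amount_unit in _MASS_IN_GRAMS and entry.ddd_unit in _MASS_IN_GRAMS:
            grams = amount * _MASS_IN_GRAMS[amount_unit]
            ddd_grams = entry.ddd_value * _MASS_IN_GRAMS[entry.ddd_unit]
            return grams / ddd_grams
        return None  # incommensurable (MU vs mass)
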