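"""Machine-readable issue log shared by all readers and linkers.

Every malformed or suspicious input row ends up here exactly once, either as a
``reject`` (the row was excluded) or a ``warn`` (the row was kept, possibly
modified).  Downstream quality reports summarise the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SEVERITIES = ("warn", "reject")


@dataclass(frozen=True)
class Issue:
    """One logged problem: where, how bad, a stable code, and prose."""

    locator: str
    severity: str
    code: str
    message: str

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES}, got {self.severity!r}")


@dataclass
class IssueLog:
    issues: list[Issue] = field(default_factory=list)

    def warn(self, locator: str, code: str, message: str) -> None:
        self.issues.append(Issue(str(locator), "warn", code, message))

    def reject(self, locator: str, code: str, message: str) -> None:
        self.issues.append(Issue(str(locator), "reject", code, message))

    def extend(self, other: "IssueLog") -> None:
        self.issues.extend(other.issues)

    @property
    def warns(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warn"]

    @property
    def rejects(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "reject"]

    def count(self, severity: str | None = None) -> int:
        if severity is None:
            return len(self.issues)
        return sum(1 for i in self.issues if i.severity == severity)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i.locator, i.severity, i.code, i.message) for i in self.issues],
            columns=["locator", "severity", "code", "message"],
        )

    def __len__(self) -> int:
        return len(self.issues)

    def __iter__(self):
        return iter(self.issues)
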