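"""Consolidation of raw workshop factors into the main-factor set.

Two expert groups (scientists, practitioners) each produce a list of raw
risk-factor labels on moderation cards.  A consolidation mapping records,
for every raw factor, one of four actions:

* ``keep``    - carried over into exactly one main factor;
* ``merge``   - several raw factors collapsed into one main factor;
* ``split``   - one raw factor divided into two or more main factors;
* ``exclude`` - dropped from the final model.

Raw labels are matched case-insensitively on whitespace-normalized text,
because they originate from hand-written cards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import MainFactor

__all__ = [
    "RawFactor",
    "ConsolidationAction",
    "ValidationReport",
    "normalize_label",
    "apply_consolidation",
    "validate_mapping",
]

SOURCE_PANELS = ("scientists", "practitioners")
ACTIONS = ("keep", "merge", "split", "exclude")


def normalize_label(label: str) -> str:
    """Trim, collapse internal whitespace, and lowercase a factor label."""
    return re.sub(r"\s+", " ", label.strip()).lower()


@dataclass(frozen=True)
class RawFactor:
    """A factor as elicited in one workshop panel."""

    label: str
    source_panel: str

    def __post_init__(self) -> None:
        if not self.label.strip():
            raise ValueError("RawFactor label must be non-empty")
        if self.source_panel not in SOURCE_PANELS:
            raise ValueError(
                f"source_panel must be one of {SOURCE_PANELS}, got {self.source_panel!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (normalize_label(self.label), self.source_panel)


@dataclass(frozen=True)
class ConsolidationAction:
    """One keep/merge/split/exclude decision over raw factors.

    ``main_targets`` are the resulting main factors.  Targets given by
    different actions but carrying the same id are unified into a single
    main factor in the output node set.
    """

    raw_labels: tuple[RawFactor, ...]
    action: str
    main_targets: tuple[MainFactor, ...] = ()
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if not self.raw_labels:
            raise ValueError("action must reference at least one raw factor")
        n = len(self.main_targets)
        if self.action == "exclude" and n != 0:
            raise ValueError("exclude action must have zero targets")
        if self.action in ("keep", "merge") and n != 1:
            raise ValueError(f"{self.action} action must have exactly one target")
        if self.action == "split":
            if n < 2:
                raise ValueError("split action must have two or more targets")
            if len({t.id for t in self.main_targets}) != n:
                raise ValueError("split targets must be distinct")


@dataclass
class ValidationReport:
    """Problems found in a consolidation mapping; empty iff valid."""

    uncovered: list[RawFactor] = field(default_factory=list)
    multiply_covered: list[RawFactor] = field(default_factory=list)
    malformed_actions: list[str] = field(default_factory=list)
    unknown_raw: list[RawFactor] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.uncovered or self.multiply_covered
                    or self.malformed_actions or self.unknown_raw)

    def summary(self) -> str:
        if self.ok:
            return "mapping valid"
        lines = []
        if self.uncovered:
            lines.append("uncovered raw factors: "
                         + ", ".join(f"{r.label!r} ({r.source_panel})" for r in self.uncovered))
        if self.multiply_covered:
            lines.append("multiply covered raw factors: "
                         + ", ".join(f"{r.label!r} ({r.source_panel})" for r in self.multiply_covered))
        if self.unknown_raw:
            lines.append("actions referencing unknown raw factors: "
                         + ", ".join(f"{r.label!r} ({r.source_panel})" for r in self.unknown_raw))
        lines.extend(self.malformed_actions)
        return "; ".join(lines)


class CoverageError(ValueError):
    """A raw factor is not covered, or covered more than once."""


def validate_mapping(raw_factors: list[RawFactor],
                     mapping: list[ConsolidationAction]) -> ValidationReport:
    """Check that a mapping covers every raw factor exactly once.

    Returns a report rather than raising; :func:`apply_consolidation`
    raises on the same conditions.  Malformed actions (a split with a
    single target, an exclude with targets) are rejected at
    :class:`ConsolidationAction` construction, so here they can only be
    reported for actions built by other means.
    """
    report = ValidationReport()
    known = {r.key for r in raw_factors}
    seen: dict[tuple[str, str], int] = {}
    for act in mapping:
        if act.action == "split" and len(act.main_targets) < 2:
            report.malformed_actions.append(
                f"split over {[r.label for r in act.raw_labels]} has "
                f"{len(act.main_targets)} target(s)")
        if act.action == "exclude" and act.main_targets:
            report.malformed_actions.append(
                f"exclude over {[r.label for r in act.raw_labels]} carries targets")
        for raw in act.raw_labels:
            if raw.key not in known:
                report.unknown_raw.append(raw)
            seen[raw.key] = seen.get(raw.key, 0) + 1
    by_key = {r.key: r for r in raw_factors}
    for raw in raw_factors:
        count = seen.get(raw.key, 0)
        if count == 0:
            report.uncovered.append(raw)
        elif count > 1:
            report.multiply_covered.append(raw)
    # dedupe unknown while preserving order
    report.unknown_raw = list(dict.fromkeys(report.unknown_raw))
    _ = by_key
    return report


def apply_consolidation(raw_factors: list[RawFactor],
                        mapping: list[ConsolidationAction]) -> list[MainFactor]:
    """Apply a consolidation mapping, returning the de-duplicated main-factor set.

    Every raw factor must appear in exactly one action.  Targets sharing an
    id across actions (e.g. scientists' and practitioners' "Housing" kept
    separately) are unified into one :class:`MainFactor`; the first
    occurrence's name/description wins.  Output order follows first
    appearance in the mapping, which keeps the fixture's published ordering.
    """
    report = validate_mapping(raw_factors, mapping)
    if report.uncovered:
        missing = ", ".join(f"{r.label!r}" for r in report.uncovered)
        raise CoverageError(f"raw factors not covered by any action: {missing}")
    if report.multiply_covered:
        dup = ", ".join(f"{r.label!r}" for r in report.multiply_covered)
        raise CoverageError(f"raw factors covered by more than one action: {dup}")
    if report.unknown_raw:
        unk = ", ".join(f"{r.label!r}" for r in report.unknown_raw)
        raise CoverageError(f"actions reference raw factors not in the input: {unk}")
    if report.malformed_actions:
        raise ValueError("; ".join(report.malformed_actions))

    out: dict[str, MainFactor] = {}
    for act in mapping:
        for target in act.main_targets:
            out.setdefault(target.id, target)
    return list(out.values())
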