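"""Mapping of MedDRA preferred terms to cardiotoxicity conditions.

Cardiotoxicity is operationalised as four medical conditions —
arrhythmias, heart failure, cardiomyopathy and myocardial infarction —
each defined by a fixed set of preferred terms (PTs).  The built-in map
contains 26 PTs (8 arrhythmia, 7 heart-failure, 4 cardiomyopathy, 7
myocardial-infarction terms).  The map is a partition: each PT belongs
to exactly one condition, and PTs outside the map belong to none.

Matching is case- and whitespace-insensitive; the canonical display form
of each PT (including its original capitalisation) is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .icsr import Database, ValidationError, normalize_pt, subset_by_drug

__all__ = [
    "Condition",
    "ConditionMap",
    "ConditionCounts",
    "load_condition_map",
    "classify_pt",
    "condition_adr_counts",
]


class Condition(str, Enum):
    ARRHYTHMIAS = "arrhythmias"
    HEART_FAILURE = "heart_failure"
    CARDIOMYOPATHY = "cardiomyopathy"
    MYOCARDIAL_INFARCTION = "myocardial_infarction"


@dataclass
class ConditionMap:
    """Lookup table from normalized PT to condition.

    ``display`` keeps the canonical (file) spelling of each PT for
    reporting; ``entries`` is keyed by :func:`normalize_pt` output.
    """

    entries: dict[str, Condition]
    display: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def classify(self, pt: str) -> Condition | None:
        return self.entries.get(normalize_pt(pt))

    def pts_for(self, condition: Condition) -> list[str]:
        """Canonical PT spellings of one condition, in map order."""
        return [
            self.display.get(k, k)
            for k, c in self.entries.items()
            if c is condition
        ]

    def normalized_pts_for(self, condition: Condition) -> set[str]:
        return {k for k, c in self.entries.items() if c is condition}

    def condition_sizes(self) -> dict[Condition, int]:
        sizes = {c: 0 for c in Condition}
        for c in self.entries.values():
            sizes[c] += 1
        return sizes


def load_condition_map(path: str | Path | None = None) -> ConditionMap:
    """Load a two-column (condition, pt) map; ``None`` loads the built-in map.

    Raises :class:`ValidationError` on unknown condition labels or on a
    PT listed under two different conditions.
    """
    if path is None:
        source = resources.files("pvsignal").joinpath("data/condition_map.csv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("condition", "pt"):
        if col not in frame.columns:
            raise ValidationError(f"condition map: missing column {col!r}")
    entries: dict[str, Condition] = {}
    display: dict[str, str] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            condition = Condition(row.condition.strip().lower())
        except ValueError:
            raise ValidationError(
                f"condition map row {i + 2}: unknown condition "
                f"{row.condition!r}"
            ) from None
        key = normalize_pt(row.pt)
        if not key:
            raise ValidationError(f"condition map row {i + 2}: empty pt")
        if key in entries and entries[key] is not condition:
            raise ValidationError(
                f"condition map row {i + 2}: PT {row.pt!r} already mapped to "
                f"{entries[key].value!r}, cannot also map to {condition.value!r}"
            )
        entries[key] = condition
        display.setdefault(key, row.pt.strip())
    return ConditionMap(entries=entries, display=display)


def classify_pt(pt: str, cmap: ConditionMap) -> Condition | None:
    """Condition of a PT, or ``None`` for PTs outside the map (total function)."""
    return cmap.classify(pt)


@dataclass
class ConditionCounts:
    """Per-condition ADR-pair and distinct-report counts for one drug."""

    pairs: dict[Condition, int]
    reports: dict[Condition, int]

    @property
    def total_pairs(self) -> int:
        return sum(self.pairs.values())


def condition_adr_counts(
    db: Database, drug: str, cmap: ConditionMap
) -> ConditionCounts:
    """Count (report, PT) pairs per condition among a drug's reports.

    A drug absent from the database yields all-zero counts.
    """
    sub = subset_by_drug(db, drug)
    pairs = {c: 0 for c in Condition}
    reports = {c: 0 for c in Condition}
    for icsr in sub.reports:
        seen: set[Condition] = set()
        for rx in icsr.reactions:
            condition = cmap.classify(rx.pt)
            if condition is not None:
                pairs[condition] += 1
                seen.add(condition)
        for condition in seen:
            reports[condition] += 1
    return ConditionCounts(pairs=pairs, reports=reports)
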