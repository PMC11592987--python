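"""Descriptive analyses of a drug's spontaneous-report profile.

Counting units follow spontaneous-reporting practice: characteristics
tables count ICSRs (one row per report), while the ADR/ICSR ratio,
seriousness, SOC and outcome distributions count deduplicated
(report, PT) pairs.  Displayed percentages are round-half-up to one
decimal; the ADR/ICSR ratio to two decimals, matching the precision at
which such tables are conventionally printed.

Outcome grouping: recovered/resolved and recovering/resolving are
*favourable*; not-recovered and resolved-with-sequelae are
*unfavourable*; fatal and unknown stand alone.  The four groups
partition the six reported outcome categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .conditions import Condition, ConditionMap
from .icsr import (
    AgeGroup,
    Database,
    Origin,
    Outcome,
    Reporter,
    Sex,
    subset_by_drug,
)

__all__ = [
    "EmptySelectionError",
    "OUTCOME_GROUPS",
    "PercentageRow",
    "PercentageTable",
    "OutcomeBreakdown",
    "round_half_up",
    "share_percent",
    "characteristics_table",
    "adr_icsr_ratio",
    "seriousness_distribution",
    "soc_distribution",
    "outcome_distribution",
    "top_pts",
]


class EmptySelectionError(ValueError):
    """The requested tally has an empty denominator."""


#: Four-group partition of the six outcome categories.
OUTCOME_GROUPS: dict[str, tuple[Outcome, ...]] = {
    "favourable": (Outcome.RECOVERED_RESOLVED, Outcome.RECOVERING_RESOLVING),
    "unfavourable": (Outcome.NOT_RECOVERED, Outcome.SEQUELAE),
    "fatal": (Outcome.FATAL,),
    "unknown": (Outcome.UNKNOWN,),
}


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, as printed tables do."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def share_percent(count: int, denominator: int, ndigits: int = 1) -> float:
    """Exact percentage of an integer count, round-half-up."""
    if denominator == 0:
        return 0.0
    quantum = Decimal(1).scaleb(-ndigits)
    exact = Decimal(100 * count) / Decimal(denominator)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PercentageRow:
    label: str
    count: int
    share_percent: float


@dataclass
class PercentageTable:
    """Labelled counts with shares of a common denominator."""

    rows: list[PercentageRow]
    denominator: int
    warning: str | None = None

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        denominator: int | None = None,
    ) -> "PercentageTable":
        if denominator is None:
            denominator = sum(counts.values())
        if sum(counts.values()) != denominator:
            raise ValueError("counts must sum to the denominator")
        warning = None
        if denominator == 0:
            warning = "zero denominator; shares reported as 0"
            warnings.warn(warning, stacklevel=3)
        rows = [
            PercentageRow(label, count, share_percent(count, denominator))
            for label, count in counts.items()
        ]
        return cls(rows=rows, denominator=denominator, warning=warning)

    def count(self, label: str) -> int:
        return next(r.count for r in self.rows if r.label == label)

    def share(self, label: str) -> float:
        return next(r.share_percent for r in self.rows if r.label == label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.rows],
                "count": [r.count for r in self.rows],
                "share_percent": [r.share_percent for r in self.rows],
            }
        )


_DIMENSIONS: dict[str, type] = {
    "age": AgeGroup,
    "sex": Sex,
    "origin": Origin,
    "reporter": Reporter,
}

_DIM_ATTR = {"age": "age_group", "sex": "sex", "origin": "origin", "reporter": "reporter"}


def characteristics_table(db: Database, drug: str) -> dict[str, PercentageTable]:
    """Per-report demographics of one drug's ICSRs.

    Returns one table per dimension (age, sex, origin, reporter); every
    category, including "not specified", is present even at zero count.
    Shares are of the drug's total ICSR count.
    """
    sub = subset_by_drug(db, drug)
    n = len(sub)
    tables: dict[str, PercentageTable] = {}
    for dim, enum_cls in _DIMENSIONS.items():
        counts = {category.value: 0 for category in enum_cls}
        attr = _DIM_ATTR[dim]
        for icsr in sub.reports:
            counts[getattr(icsr, attr).value] += 1
        tables[dim] = PercentageTable.from_counts(counts, denominator=n)
    return tables


def adr_icsr_ratio(db: Database, drug: str) -> float:
    """Mean number of distinct reaction terms per report, 2 decimals."""
    sub = subset_by_drug(db, drug)
    if len(sub) == 0:
        raise EmptySelectionError(f"no reports for drug {drug!r}: ratio undefined")
    pairs = sum(len(r.reactions) for r in sub.reports)
    return round_half_up(pairs / len(sub), 2)


def seriousness_distribution(db: Database, drug: str) -> PercentageTable:
    """Split of a drug's ADR pairs into serious and non-serious."""
    sub = subset_by_drug(db, drug)
    counts = {"serious": 0, "non-serious": 0}
    for icsr in sub.reports:
        for rx in icsr.reactions:
            counts["serious" if rx.serious else "non-serious"] += 1
    if sum(counts.values()) == 0:
        raise EmptySelectionError(f"no ADR pairs for drug {drug!r}")
    return PercentageTable.from_counts(counts)


def soc_distribution(db: Database, drug: str) -> PercentageTable:
    """ADR pairs grouped by System Organ Class, alphabetical order."""
    sub = subset_by_drug(db, drug)
    counts: dict[str, int] = {}
    for icsr in sub.reports:
        for rx in icsr.reactions:
            counts[rx.soc] = counts.get(rx.soc, 0) + 1
    if not counts:
        raise EmptySelectionError(f"no ADR pairs for drug {drug!r}")
    ordered = {soc: counts[soc] for soc in sorted(counts)}
    return PercentageTable.from_counts(ordered)


@dataclass
class OutcomeBreakdown:
    """Outcome profile of one condition's ADR pairs for one drug."""

    groups: PercentageTable
    outcome_counts: dict[Outcome, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.groups.denominator


def outcome_distribution(
    db: Database,
    drug: str,
    condition: Condition,
    cmap: ConditionMap,
) -> OutcomeBreakdown:
    """Outcomes of the ADR pairs mapping to one cardiotoxicity condition.

    Returns four-group shares (favourable / unfavourable / fatal /
    unknown) plus the raw six-category counts.  A condition with zero
    pairs yields a zero table flagged with a warning rather than an
    error, since panels iterate all four conditions.
    """
    condition = Condition(condition)
    sub = subset_by_drug(db, drug)
    outcome_counts = {o: 0 for o in Outcome}
    for icsr in sub.reports:
        for rx in icsr.reactions:
            if cmap.classify(rx.pt) is condition:
                outcome_counts[rx.outcome] += 1
    group_counts = {
        group: sum(outcome_counts[o] for o in members)
        for group, members in OUTCOME_GROUPS.items()
    }
    return OutcomeBreakdown(
        groups=PercentageTable.from_counts(group_counts),
        outcome_counts=outcome_counts,
    )


def top_pts(
    db: Database,
    drug: str,
    condition: Condition,
    cmap: ConditionMap,
    k: int = 10,
) -> list[tuple[str, int]]:
    """The condition's ``k`` most-reported PTs for one drug.

    Sorted by descending ADR-pair count, ties broken alphabetically on
    the canonical PT spelling.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    condition = Condition(condition)
    sub = subset_by_drug(db, drug)
    counts: dict[str, int] = {}
    for icsr in sub.reports:
        for rx in icsr.reactions:
            if cmap.classify(rx.pt) is condition:
                counts[rx.pt_norm] = counts.get(rx.pt_norm, 0) + 1
    ranked = sorted(
        (
            (cmap.display.get(pt_norm, pt_norm), n)
            for pt_norm, n in counts.items()
        ),
        key=lambda item: (-item[1], item[0].casefold()),
    )
    return ranked[:k]
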