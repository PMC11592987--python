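"""Case/non-case disproportionality analysis: the reporting odds ratio.

For an index drug and a comparator drug, ADR pairs are split by
membership in an event set (a cardiotoxicity condition's PTs, or a whole
System Organ Class), giving the 2x2 table

    ==========  =======  ===========
                event    non-event
    ==========  =======  ===========
    index       a        b
    comparator  c        d
    ==========  =======  ===========

The reporting odds ratio is ROR = (a*d)/(b*c).  Confidence limits use
the Woolf (log) method: SE(log ROR) = sqrt(1/a + 1/b + 1/c + 1/d), with
normal quantiles; the two-sided p-value is the normal tail of
log(ROR)/SE.  If any cell is zero, the Haldane-Anscombe correction adds
0.5 to all four cells (flagged on the result).

A *signal of disproportionate reporting* follows the EMA criterion: the
lower bound of the 95% CI strictly exceeds 1 and the event is supported
by at least 5 distinct index-drug reports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .conditions import Condition, ConditionMap
from .descriptive import round_half_up
from .icsr import Database, normalize_pt, subset_by_drug

__all__ = [
    "UndefinedEstimateError",
    "ContingencyTable",
    "RORResult",
    "PanelEntry",
    "SocEvent",
    "build_contingency",
    "compute_ror",
    "assess_signal",
    "significance_stars",
    "default_events",
    "ror_panel",
    "panel_to_frame",
]


class UndefinedEstimateError(ValueError):
    """A zero cell with the continuity correction disabled."""


@dataclass(frozen=True)
class ContingencyTable:
    """Case/non-case 2x2 counts plus the index drug's event ICSR count.

    ``a``/``b`` are the index drug's event and non-event ADR pairs,
    ``c``/``d`` the comparator's.  ``n_icsr_index`` counts distinct
    index-drug reports containing at least one event PT; it feeds the
    >=5-ICSR arm of the signal criterion.
    """

    a: int
    b: int
    c: int
    d: int
    n_icsr_index: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.n_icsr_index) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n_icsr_index > self.a:
            raise ValueError("n_icsr_index cannot exceed the event pair count a")

    def swapped(self) -> "ContingencyTable":
        """Index and comparator exchanged (n_icsr re-anchored to c)."""
        return ContingencyTable(
            a=self.c, b=self.d, c=self.a, d=self.b, n_icsr_index=self.c
        )


@dataclass
class RORResult:
    """Point estimate, Woolf CI, p-value and EMA signal flag."""

    ror: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    table: ContingencyTable
    corrected: bool
    signal: bool
    event: str | None = None
    comparator: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class SocEvent:
    """Event defined as every PT reported under one System Organ Class."""

    soc: str


@dataclass
class PanelEntry:
    event: str
    comparator: str
    result: RORResult | None
    error: str | None = None


def build_contingency(
    db: Database,
    index_drug: str,
    comparator_drug: str,
    event_pts: Iterable[str] | None = None,
    *,
    event_soc: str | None = None,
    unit: str = "pair",
) -> ContingencyTable:
    """Classify every ADR pair of both drugs into the 2x2 table.

    The event is either an explicit PT set (``event_pts``, matched
    case-insensitively) or a whole SOC (``event_soc``).  ``unit`` selects
    the counting unit for a-d: ``"pair"`` counts (report, PT) pairs,
    ``"report"`` counts reports with/without an event term.  Reports
    mentioning both drugs contribute to both arms.
    """
    from .icsr import normalize_drug_name

    if normalize_drug_name(index_drug) == normalize_drug_name(comparator_drug):
        raise ValueError("index and comparator drugs must differ")
    if (event_pts is None) == (event_soc is None):
        raise ValueError("exactly one of event_pts / event_soc must be given")
    if unit not in ("pair", "report"):
        raise ValueError("unit must be 'pair' or 'report'")

    pts: set[str] | None = None
    if event_pts is not None:
        pts = {normalize_pt(p) for p in event_pts}
        if not pts:
            raise ValueError("event_pts must be non-empty")

    def is_event(rx) -> bool:
        if pts is not None:
            return rx.pt_norm in pts
        return rx.soc == event_soc

    def tally(drug: str) -> tuple[int, int, int]:
        sub = subset_by_drug(db, drug)
        event_pairs = 0
        other_pairs = 0
        event_reports = 0
        for icsr in sub.reports:
            hit = False
            for rx in icsr.reactions:
                if is_event(rx):
                    event_pairs += 1
                    hit = True
                else:
                    other_pairs += 1
            if hit:
                event_reports += 1
        if unit == "report":
            return event_reports, len(sub) - event_reports, event_reports
        return event_pairs, other_pairs, event_reports

    a, b, n_icsr = tally(index_drug)
    c, d, _ = tally(comparator_drug)
    return ContingencyTable(a=a, b=b, c=c, d=d, n_icsr_index=n_icsr)


def compute_ror(
    table: ContingencyTable,
    alpha: float = 0.05,
    continuity: bool = True,
    min_icsr: int = 5,
) -> RORResult:
    """Woolf log-method ROR with CI, p-value and signal flag.

    With ``continuity`` enabled, a zero anywhere in the table triggers
    the Haldane-Anscombe correction (0.5 added to all four cells);
    disabled, a zero cell raises :class:`UndefinedEstimateError`.
    Estimate and CI bounds are kept at full precision; table output
    rounds them to the conventional 4 decimals.
    """
    import math

    cells = [table.a, table.b, table.c, table.d]
    corrected = False
    if min(cells) == 0:
        if not continuity:
            raise UndefinedEstimateError(
                f"zero cell in {cells} with continuity correction disabled"
            )
        cells = [x + 0.5 for x in cells]
        corrected = True
    a, b, c, d = cells

    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    log_ror = math.log(ror)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    p_value = 2 * stats.norm.sf(abs(log_ror) / se)

    signal = ci_low > 1 and table.n_icsr_index >= min_icsr
    return RORResult(
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p_value),
        alpha=alpha,
        table=table,
        corrected=corrected,
        signal=signal,
    )


def assess_signal(result: RORResult, min_icsr: int = 5) -> bool:
    """EMA rule: lower CI bound strictly above 1 and >= ``min_icsr`` ICSRs."""
    return result.ci_low > 1 and result.table.n_icsr_index >= min_icsr


def significance_stars(p_value: float) -> str:
    """Figure-caption star convention for two-sided p-values."""
    if p_value <= 0.0001:
        return "****"
    if p_value <= 0.001:
        return "***"
    if p_value <= 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


EventSpec = Condition | SocEvent | Sequence[str]

#: SOC label used for the SOC-level cardiac analysis.
CARDIAC_SOC = "Cardiac disorders"


def default_events(
    cmap: ConditionMap, include_soc: bool = True
) -> dict[str, EventSpec]:
    """The study's event set: the four conditions plus the cardiac SOC."""
    events: dict[str, EventSpec] = {c.value: c for c in Condition}
    if include_soc:
        events["cardiac_disorders_soc"] = SocEvent(CARDIAC_SOC)
    return events


def _resolve_event(
    spec: EventSpec, cmap: ConditionMap | None
) -> tuple[set[str] | None, str | None]:
    if isinstance(spec, SocEvent):
        return None, spec.soc
    if isinstance(spec, Condition):
        if cmap is None:
            raise ValueError("a ConditionMap is required for condition events")
        return cmap.normalized_pts_for(spec), None
    return {normalize_pt(p) for p in spec}, None


def ror_panel(
    db: Database,
    index_drug: str,
    comparators: Sequence[str],
    events: Mapping[str, EventSpec],
    cmap: ConditionMap | None = None,
    *,
    alpha: float = 0.05,
    continuity: bool = True,
    min_icsr: int = 5,
    unit: str = "pair",
) -> list[PanelEntry]:
    """One ROR per (event, comparator) against a common index drug.

    Failures in individual cells (e.g. a zero cell with continuity
    disabled) are recorded on the entry rather than aborting the panel.
    """
    from .icsr import normalize_drug_name

    if not comparators:
        raise ValueError("at least one comparator is required")
    if any(
        normalize_drug_name(c) == normalize_drug_name(index_drug)
        for c in comparators
    ):
        raise ValueError("comparators must differ from the index drug")
    entries: list[PanelEntry] = []
    for event_label, spec in events.items():
        pts, soc = _resolve_event(spec, cmap)
        for comparator in comparators:
            try:
                table = build_contingency(
                    db,
                    index_drug,
                    comparator,
                    event_pts=pts,
                    event_soc=soc,
                    unit=unit,
                )
                result = compute_ror(
                    table, alpha=alpha, continuity=continuity, min_icsr=min_icsr
                )
                result = replace(result, event=event_label, comparator=comparator)
                entries.append(PanelEntry(event_label, comparator, result))
            except (ValueError, ZeroDivisionError) as exc:
                entries.append(
                    PanelEntry(event_label, comparator, None, error=str(exc))
                )
    return entries


def panel_to_frame(entries: Sequence[PanelEntry]) -> pd.DataFrame:
    """Flatten a panel into the forest-table CSV layout."""
    rows = []
    for e in entries:
        if e.result is None:
            rows.append(
                {
                    "event": e.event,
                    "comparator": e.comparator,
                    "error": e.error,
                }
            )
            continue
        r = e.result
        rows.append(
            {
                "event": e.event,
                "comparator": e.comparator,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "n_icsr": r.table.n_icsr_index,
                "ror": round_half_up(r.ror, 4),
                "ci_low": round_half_up(r.ci_low, 4),
                "ci_high": round_half_up(r.ci_high, 4),
                "p_value": r.p_value,
                "stars": r.stars,
                "corrected": r.corrected,
                "signal": r.signal,
                "error": "",
            }
        )
    return pd.DataFrame(rows)
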