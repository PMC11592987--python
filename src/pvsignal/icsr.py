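"""Domain model and relational CSV I/O for Individual Case Safety Reports.

A spontaneous-report database is represented as a collection of
:class:`ICSR` objects, each carrying demographics, reporter metadata and
the linked drug entries and adverse-reaction terms.  On disk the database
is three flat CSV tables (``reports.csv``, ``drugs.csv``,
``reactions.csv``) joined on ``report_id``.

An "ADR" throughout this package is one deduplicated (report, preferred
term) pair: the same MedDRA PT listed twice on one report counts once,
matching how spontaneous-report systems count a reaction term once per
case.  Deduplication happens at :class:`ICSR` construction time, so every
downstream tally can treat a report's reaction list as a set of PTs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "ValidationError",
    "ReferentialIntegrityError",
    "AgeGroup",
    "Sex",
    "Origin",
    "Reporter",
    "Role",
    "Outcome",
    "DrugEntry",
    "Reaction",
    "ICSR",
    "Database",
    "normalize_drug_name",
    "normalize_pt",
    "read_database",
    "write_database",
    "subset_by_drug",
]


class ValidationError(ValueError):
    """A value in a database file or object violates the schema."""


class ReferentialIntegrityError(ValidationError):
    """A drug or reaction row references a report_id with no reports row."""


_WS = re.compile(r"\s+")
# en dash, em dash and minus sign occasionally leak into age-group labels
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})


def _collapse_ws(text: str) -> str:
    return _WS.sub(" ", str(text).strip())


def normalize_drug_name(name: str) -> str:
    """Canonical active-substance form: uppercased, trimmed, single spaces."""
    return _collapse_ws(name).upper()


def normalize_pt(pt: str) -> str:
    """Canonical PT form for matching: trimmed, single spaces, casefolded."""
    return _collapse_ws(pt).casefold()


class AgeGroup(str, Enum):
    NS = "NS"
    M0_1 = "0-1M"
    M2_2Y = "2M-2Y"
    Y3_11 = "3-11Y"
    Y12_17 = "12-17Y"
    Y18_64 = "18-64Y"
    Y65_85 = "65-85Y"
    OVER_85 = "85+"


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"
    NS = "NS"


class Origin(str, Enum):
    EEA = "EEA"
    NON_EEA = "NON-EEA"
    NS = "NS"


class Reporter(str, Enum):
    HP = "HP"
    NON_HP = "NON-HP"
    NS = "NS"


class Role(str, Enum):
    SUSPECT = "SUSPECT"
    INTERACTING = "INTERACTING"
    CONCOMITANT = "CONCOMITANT"


class Outcome(str, Enum):
    RECOVERED_RESOLVED = "R_RS"
    RECOVERING_RESOLVING = "RG_RSG"
    NOT_RECOVERED = "NR_NRS"
    SEQUELAE = "SEQUELAE"
    FATAL = "FATAL"
    UNKNOWN = "UNKNOWN"


def _coerce_enum(enum_cls, value, *, context: str = ""):
    if isinstance(value, enum_cls):
        return value
    raw = _collapse_ws(str(value)).translate(_DASHES).upper()
    # enum values are already uppercase CSV literals
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        where = f" ({context})" if context else ""
        raise ValidationError(
            f"unknown {enum_cls.__name__} literal {value!r}{where}; "
            f"expected one of: {allowed}"
        ) from None


@dataclass
class DrugEntry:
    """One drug mention on a report, with its causal role."""

    drug_name: str
    role: Role

    def __post_init__(self) -> None:
        self.drug_name = normalize_drug_name(self.drug_name)
        if not self.drug_name:
            raise ValidationError("drug_name must be non-empty")
        self.role = _coerce_enum(Role, self.role)


@dataclass
class Reaction:
    """One adverse-event term on a report."""

    pt: str
    soc: str
    serious: bool
    outcome: Outcome

    def __post_init__(self) -> None:
        self.pt = _collapse_ws(self.pt)
        if not self.pt:
            raise ValidationError("pt must be non-empty")
        self.soc = _collapse_ws(self.soc)
        self.serious = bool(self.serious)
        self.outcome = _coerce_enum(Outcome, self.outcome)

    @property
    def pt_norm(self) -> str:
        return normalize_pt(self.pt)


@dataclass
class ICSR:
    """One spontaneous report: demographics plus linked drugs and reactions.

    Reactions are deduplicated by normalized PT on construction (first
    occurrence wins), so ``len(reactions)`` equals the report's ADR-pair
    count.
    """

    report_id: str
    age_group: AgeGroup
    sex: Sex
    origin: Origin
    reporter: Reporter
    drugs: list[DrugEntry]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        self.report_id = str(self.report_id).strip()
        if not self.report_id:
            raise ValidationError("report_id must be non-empty")
        self.age_group = _coerce_enum(AgeGroup, self.age_group)
        self.sex = _coerce_enum(Sex, self.sex)
        self.origin = _coerce_enum(Origin, self.origin)
        self.reporter = _coerce_enum(Reporter, self.reporter)
        if not self.drugs:
            raise ValidationError(f"report {self.report_id!r} has no drug entries")
        if not self.reactions:
            raise ValidationError(f"report {self.report_id!r} has no reactions")
        seen: set[str] = set()
        deduped: list[Reaction] = []
        for rx in self.reactions:
            if rx.pt_norm not in seen:
                seen.add(rx.pt_norm)
                deduped.append(rx)
        self.reactions = deduped

    def mentions(self, drug_name: str, roles: frozenset[Role]) -> bool:
        name = normalize_drug_name(drug_name)
        return any(d.drug_name == name and d.role in roles for d in self.drugs)


@dataclass
class Database:
    """An in-memory ICSR database with free-text provenance metadata."""

    reports: list[ICSR]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ids = [r.report_id for r in self.reports]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            for rid in ids:
                if rid in seen:
                    raise ValidationError(f"duplicate report_id {rid!r}")
                seen.add(rid)
        self._pairs_cache: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[ICSR]:
        return iter(self.reports)

    def drug_names(self) -> set[str]:
        return {d.drug_name for r in self.reports for d in r.drugs}

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "report_id": [r.report_id for r in self.reports],
                "age_group": [r.age_group.value for r in self.reports],
                "sex": [r.sex.value for r in self.reports],
                "origin": [r.origin.value for r in self.reports],
                "reporter": [r.reporter.value for r in self.reports],
            }
        )

    def pairs_frame(self) -> pd.DataFrame:
        """One row per (report, PT) pair, with seriousness and outcome."""
        if self._pairs_cache is None:
            rows = {
                "report_id": [],
                "pt": [],
                "pt_norm": [],
                "soc": [],
                "serious": [],
                "outcome": [],
            }
            for r in self.reports:
                for rx in r.reactions:
                    rows["report_id"].append(r.report_id)
                    rows["pt"].append(rx.pt)
                    rows["pt_norm"].append(rx.pt_norm)
                    rows["soc"].append(rx.soc)
                    rows["serious"].append(rx.serious)
                    rows["outcome"].append(rx.outcome.value)
            self._pairs_cache = pd.DataFrame(rows)
        return self._pairs_cache


_REPORT_COLS = ["report_id", "age_group", "sex", "origin", "reporter"]
_DRUG_COLS = ["report_id", "drug_name", "role"]
_REACTION_COLS = ["report_id", "pt", "soc", "serious", "outcome"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return frame


def _parse_serious(raw: str, *, context: str) -> bool:
    value = raw.strip().upper()
    if value == "TRUE":
        return True
    if value == "FALSE":
        return False
    raise ValidationError(
        f"invalid serious literal {raw!r} ({context}); expected TRUE or FALSE"
    )


def read_database(
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> Database:
    """Read and validate the three-table CSV representation.

    Raises :class:`ValidationError` on unknown enum literals (naming the
    file, row and column) and :class:`ReferentialIntegrityError` on drug
    or reaction rows whose ``report_id`` has no reports row.  Row numbers
    in messages are 1-based file lines (the header is line 1).
    """
    reports_df = _read_csv(reports_path, _REPORT_COLS)
    drugs_df = _read_csv(drugs_path, _DRUG_COLS)
    reactions_df = _read_csv(reactions_path, _REACTION_COLS)

    known_ids = set(reports_df["report_id"])
    if len(known_ids) != len(reports_df):
        dupes = reports_df["report_id"][reports_df["report_id"].duplicated()]
        raise ValidationError(
            f"{reports_path}: duplicate report_id {dupes.iloc[0]!r}"
        )

    drugs_by_report: dict[str, list[DrugEntry]] = {}
    for i, row in enumerate(drugs_df.itertuples(index=False)):
        ctx = f"{drugs_path} row {i + 2}"
        if row.report_id not in known_ids:
            raise ReferentialIntegrityError(
                f"{ctx}: report_id {row.report_id!r} has no reports row"
            )
        entry = DrugEntry(
            drug_name=row.drug_name,
            role=_coerce_enum(Role, row.role, context=f"{ctx}, column role"),
        )
        drugs_by_report.setdefault(row.report_id, []).append(entry)

    reactions_by_report: dict[str, list[Reaction]] = {}
    for i, row in enumerate(reactions_df.itertuples(index=False)):
        ctx = f"{reactions_path} row {i + 2}"
        if row.report_id not in known_ids:
            raise ReferentialIntegrityError(
                f"{ctx}: report_id {row.report_id!r} has no reports row"
            )
        rx = Reaction(
            pt=row.pt,
            soc=row.soc,
            serious=_parse_serious(row.serious, context=f"{ctx}, column serious"),
            outcome=_coerce_enum(
                Outcome, row.outcome, context=f"{ctx}, column outcome"
            ),
        )
        reactions_by_report.setdefault(row.report_id, []).append(rx)

    reports: list[ICSR] = []
    for i, row in enumerate(reports_df.itertuples(index=False)):
        ctx = f"{reports_path} row {i + 2}"
        if row.report_id not in drugs_by_report:
            raise ValidationError(f"{ctx}: report has no drug rows")
        if row.report_id not in reactions_by_report:
            raise ValidationError(f"{ctx}: report has no reaction rows")
        reports.append(
            ICSR(
                report_id=row.report_id,
                age_group=_coerce_enum(
                    AgeGroup, row.age_group, context=f"{ctx}, column age_group"
                ),
                sex=_coerce_enum(Sex, row.sex, context=f"{ctx}, column sex"),
                origin=_coerce_enum(
                    Origin, row.origin, context=f"{ctx}, column origin"
                ),
                reporter=_coerce_enum(
                    Reporter, row.reporter, context=f"{ctx}, column reporter"
                ),
                drugs=drugs_by_report[row.report_id],
                reactions=reactions_by_report[row.report_id],
            )
        )

    return Database(
        reports=reports,
        provenance={"source": str(reports_path)},
    )


def write_database(
    db: Database,
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> None:
    """Write the three CSVs with a fixed column order and UTF-8 encoding.

    Output is byte-stable: re-writing the same database yields identical
    files, and ``read_database`` on the output reproduces the input
    field-by-field.
    """
    drug_rows = []
    reaction_rows = []
    for r in db.reports:
        for d in r.drugs:
            drug_rows.append((r.report_id, d.drug_name, d.role.value))
        for rx in r.reactions:
            reaction_rows.append(
                (
                    r.report_id,
                    rx.pt,
                    rx.soc,
                    "TRUE" if rx.serious else "FALSE",
                    rx.outcome.value,
                )
            )
    db.reports_frame().to_csv(
        reports_path, index=False, lineterminator="\n", encoding="utf-8"
    )
    pd.DataFrame(drug_rows, columns=_DRUG_COLS).to_csv(
        drugs_path, index=False, lineterminator="\n", encoding="utf-8"
    )
    pd.DataFrame(reaction_rows, columns=_REACTION_COLS).to_csv(
        reactions_path, index=False, lineterminator="\n", encoding="utf-8"
    )


ALL_ROLES: frozenset[Role] = frozenset(Role)


def subset_by_drug(
    db: Database,
    drug_name: str,
    roles: Iterable[Role | str] = ALL_ROLES,
) -> Database:
    """Reports mentioning ``drug_name`` in any of the given roles.

    Reports are returned whole (all reactions retained), because the
    case/non-case design conditions on the drug mention, not on
    individual reactions.
    """
    role_set = frozenset(_coerce_enum(Role, r) for r in roles)
    if not role_set:
        raise ValueError("roles must be a non-empty subset of Role")
    selected = [r for r in db.reports if r.mentions(drug_name, role_set)]
    return Database(
        reports=selected,
        provenance={**db.provenance, "subset": normalize_drug_name(drug_name)},
    )
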