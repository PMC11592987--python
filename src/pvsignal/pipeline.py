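"""End-to-end pipeline: database in, the full table set out.

`run_pipeline` ties the stages together: load (or generate) an ICSR
database, run every descriptive analysis for the index drug, build the
ROR panel against the comparators, and write one CSV per table plus a
run log (seed, config hash, row counts).  Outputs are deterministic for
a fixed configuration and are only overwritten under ``force``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .conditions import Condition, condition_adr_counts, load_condition_map
from .descriptive import (
    adr_icsr_ratio,
    characteristics_table,
    outcome_distribution,
    seriousness_distribution,
    soc_distribution,
    top_pts,
)
from .disproportionality import default_events, panel_to_frame, ror_panel
from .icsr import Database, ValidationError, read_database, write_database
from .synthetic import GeneratorConfig, generate_database

log = logging.getLogger("pvsignal")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``input_paths`` (reports/drugs/reactions CSVs) or
    ``generator_config`` must be supplied.
    """

    index_drug: str
    comparators: list[str] = field(default_factory=list)
    input_paths: tuple[str, str, str] | None = None
    generator_config: GeneratorConfig | None = None
    condition_map_path: str | None = None
    output_dir: str = "pvsignal_out"
    unit: str = "pair"
    continuity: bool = True
    alpha: float = 0.05
    min_icsr: int = 5
    include_soc_event: bool = True
    top_k: int = 10
    force: bool = False
    write_database_copy: bool = False

    def validate(self) -> None:
        if (self.input_paths is None) == (self.generator_config is None):
            raise ValidationError(
                "exactly one of input_paths / generator_config must be set"
            )


def _config_hash(rc: RunConfig) -> str:
    def default(obj):
        if hasattr(obj, "__dict__"):
            return obj.__dict__
        if hasattr(obj, "value"):
            return obj.value
        return str(obj)

    payload = json.dumps(rc, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return len(frame)


def run_pipeline(rc: RunConfig) -> dict[str, int]:
    """Run every stage and write the table set; returns row counts per file."""
    rc.validate()
    out = Path(rc.output_dir)
    if out.exists() and any(out.iterdir()) and not rc.force:
        raise ValidationError(
            f"output directory {out} is not empty; pass force=True to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage load: reading inputs")
    if rc.input_paths is not None:
        db = read_database(*rc.input_paths)
        seed = None
    else:
        db = generate_database(rc.generator_config)
        seed = rc.generator_config.seed
    if len(db) == 0:
        raise ValidationError("stage load: database contains no reports")

    cmap = load_condition_map(rc.condition_map_path)
    drug = rc.index_drug
    counts: dict[str, int] = {}

    if rc.write_database_copy:
        write_database(
            db,
            out / "reports.csv",
            out / "drugs.csv",
            out / "reactions.csv",
        )

    log.info("stage describe: characteristics / ratio / seriousness / SOC")
    tables = characteristics_table(db, drug)
    char_rows = []
    for dim in ("age", "sex", "origin", "reporter"):
        for row in tables[dim].rows:
            char_rows.append(
                {
                    "dimension": dim,
                    "label": row.label,
                    "count": row.count,
                    "share_percent": row.share_percent,
                }
            )
    counts["characteristics.csv"] = _write(
        pd.DataFrame(char_rows), out / "characteristics.csv"
    )

    ratio = adr_icsr_ratio(db, drug)
    counts["seriousness.csv"] = _write(
        seriousness_distribution(db, drug).to_frame(), out / "seriousness.csv"
    )
    counts["soc_distribution.csv"] = _write(
        soc_distribution(db, drug).to_frame(), out / "soc_distribution.csv"
    )

    log.info("stage outcomes: per-condition outcome tables")
    outcome_rows = []
    for condition in Condition:
        breakdown = outcome_distribution(db, drug, condition, cmap)
        for row in breakdown.groups.rows:
            outcome_rows.append(
                {
                    "condition": condition.value,
                    "kind": "group",
                    "label": row.label,
                    "count": row.count,
                    "share_percent": row.share_percent,
                }
            )
        for outcome, n in breakdown.outcome_counts.items():
            outcome_rows.append(
                {
                    "condition": condition.value,
                    "kind": "outcome",
                    "label": outcome.value,
                    "count": n,
                    "share_percent": "",
                }
            )
    counts["outcomes_by_condition.csv"] = _write(
        pd.DataFrame(outcome_rows), out / "outcomes_by_condition.csv"
    )

    top_rows = []
    for condition in Condition:
        for pt, n in top_pts(db, drug, condition, cmap, k=rc.top_k):
            top_rows.append({"condition": condition.value, "pt": pt, "count": n})
    counts["top_pts.csv"] = _write(pd.DataFrame(top_rows), out / "top_pts.csv")

    if rc.comparators:
        log.info("stage signal: ROR panel")
        events = default_events(cmap, include_soc=rc.include_soc_event)
        entries = ror_panel(
            db,
            drug,
            rc.comparators,
            events,
            cmap,
            alpha=rc.alpha,
            continuity=rc.continuity,
            min_icsr=rc.min_icsr,
            unit=rc.unit,
        )
        counts["ror_panel.csv"] = _write(
            panel_to_frame(entries), out / "ror_panel.csv"
        )

    condition_counts = condition_adr_counts(db, drug, cmap)
    run_log = {
        "seed": seed,
        "config_hash": _config_hash(rc),
        "index_drug": drug,
        "n_reports": len(db),
        "adr_icsr_ratio": ratio,
        "condition_adr_pairs": {
            c.value: n for c, n in condition_counts.pairs.items()
        },
        "row_counts": counts,
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return counts
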