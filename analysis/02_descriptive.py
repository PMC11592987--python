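"""Descriptive analysis of the capecitabine safety profile.

Stage 1 runs on the deterministic study-shaped database (the published
capecitabine aggregates realised exactly) and writes the full table set:
report characteristics, ADR/ICSR ratio, seriousness, SOC distribution,
per-condition outcome tables and top-PT rankings.  Stage 2 compares the
ADR/ICSR ratio and seriousness across the six drugs of the synthetic
comparator database from analysis/01_simulate.py (if present).

Run:  python analysis/02_descriptive.py
"""

from pathlib import Path

import pandas as pd

import pvsignal as pv
from pvsignal.synthetic import study_shaped_fixture

CAP = "CAPECITABINE"
OUT = Path("results/descriptive")
DATA = Path("scratch/synthetic_db")


def fixture_tables() -> None:
    db = study_shaped_fixture("full")
    cmap = pv.load_condition_map()
    OUT.mkdir(parents=True, exist_ok=True)

    rows = []
    for dim, table in pv.characteristics_table(db, CAP).items():
        for r in table.rows:
            rows.append({"dimension": dim, "label": r.label,
                         "count": r.count, "share_percent": r.share_percent})
    pd.DataFrame(rows).to_csv(OUT / "characteristics.csv", index=False)

    pv.seriousness_distribution(db, CAP).to_frame().to_csv(
        OUT / "seriousness.csv", index=False)
    pv.soc_distribution(db, CAP).to_frame().to_csv(
        OUT / "soc_distribution.csv", index=False)

    outcome_rows, top_rows = [], []
    for condition in pv.Condition:
        breakdown = pv.outcome_distribution(db, CAP, condition, cmap)
        for r in breakdown.groups.rows:
            outcome_rows.append({"condition": condition.value, "label": r.label,
                                 "count": r.count, "share_percent": r.share_percent})
        for pt, n in pv.top_pts(db, CAP, condition, cmap, k=10):
            top_rows.append({"condition": condition.value, "pt": pt, "count": n})
    pd.DataFrame(outcome_rows).to_csv(OUT / "outcomes_by_condition.csv", index=False)
    pd.DataFrame(top_rows).to_csv(OUT / "top_pts.csv", index=False)

    counts = pv.condition_adr_counts(db, CAP, cmap)
    mi = pv.outcome_distribution(db, CAP, pv.Condition.MYOCARDIAL_INFARCTION, cmap)
    hf = pv.outcome_distribution(db, CAP, pv.Condition.HEART_FAILURE, cmap)
    print(f"capecitabine arm: {len(db):,} ICSRs, "
          f"{pv.adr_icsr_ratio(db, CAP):.2f} ADRs per ICSR, "
          f"{pv.seriousness_distribution(db, CAP).share('serious')}% serious")
    print(f"cardiac-condition ADRs: {counts.total_pairs:,} "
          f"(MI {counts.pairs[pv.Condition.MYOCARDIAL_INFARCTION]}, "
          f"HF {counts.pairs[pv.Condition.HEART_FAILURE]}, "
          f"cardiomyopathy {counts.pairs[pv.Condition.CARDIOMYOPATHY]}, "
          f"arrhythmias {counts.pairs[pv.Condition.ARRHYTHMIAS]})")
    print(f"MI outcomes: {mi.groups.share('favourable')}% favourable, "
          f"{mi.groups.share('fatal')}% fatal; "
          f"HF fatal {hf.groups.share('fatal')}%")


def comparator_tables() -> None:
    paths = [DATA / n for n in ("reports.csv", "drugs.csv", "reactions.csv")]
    if not all(p.exists() for p in paths):
        print("synthetic comparator database not found; "
              "run analysis/01_simulate.py first")
        return
    db = pv.read_database(*paths)
    rows = []
    for drug in sorted(db.drug_names()):
        rows.append({
            "drug": drug,
            "n_reports": len(pv.subset_by_drug(db, drug)),
            "adr_icsr_ratio": pv.adr_icsr_ratio(db, drug),
            "serious_pct": pv.seriousness_distribution(db, drug).share("serious"),
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "comparator_overview.csv", index=False)
    print("\ncomparator overview (synthetic):")
    print(frame.to_string(index=False))


if __name__ == "__main__":
    fixture_tables()
    comparator_tables()
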