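"""Generate the synthetic ICSR database used by the downstream analyses.

Draws a scaled-down six-drug database (5% of the real per-drug report
volumes, ~10,700 reports) with cardiac-condition reporting enriched for
the two fluoropyrimidines, so the disproportionality stage has real
signals to find.  The three CSV tables land under scratch/synthetic_db/
(regenerated on demand; not part of the results).

Run:  python analysis/01_simulate.py [seed]
"""

import dataclasses
import sys
from pathlib import Path

import pvsignal as pv
from pvsignal.synthetic import default_config, generate_database

SCALE = 0.05
OUT = Path("scratch/synthetic_db")

#: Cardiac-condition odds multipliers: fluoropyrimidines report cardiac
#: events more often than the comparator drugs.
ENRICHMENT = [
    ("CAPECITABINE", "myocardial_infarction", 4.0),
    ("FLUOROURACIL", "myocardial_infarction", 3.5),
    ("CAPECITABINE", "heart_failure", 3.0),
    ("FLUOROURACIL", "heart_failure", 3.0),
    ("CAPECITABINE", "cardiomyopathy", 3.5),
    ("FLUOROURACIL", "cardiomyopathy", 2.5),
    ("CAPECITABINE", "arrhythmias", 1.5),
    ("FLUOROURACIL", "arrhythmias", 2.0),
]


def build_config(seed: int):
    cfg = default_config(scale=SCALE, seed=seed)
    return dataclasses.replace(cfg, enrichment=list(ENRICHMENT))


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 1
    cfg = build_config(seed)
    db = generate_database(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    pv.write_database(
        db, OUT / "reports.csv", OUT / "drugs.csv", OUT / "reactions.csv"
    )
    print(f"seed {seed}: generated {len(db)} reports across "
          f"{len(cfg.drugs)} drugs -> {OUT}")
    for dv in cfg.drugs:
        ratio = pv.adr_icsr_ratio(db, dv.name)
        print(f"  {dv.name:<13} {dv.n_reports:>6} reports, "
              f"{ratio:.2f} ADRs/ICSR")


if __name__ == "__main__":
    main()
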