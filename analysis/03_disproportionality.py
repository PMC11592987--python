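"""Disproportionality analysis: ROR panels for the two fluoropyrimidines.

For capecitabine and for 5-fluorouracil as index drugs, computes the
reporting odds ratio against every other study drug, for the cardiac
SOC and each of the four cardiotoxicity conditions, on the synthetic
database from analysis/01_simulate.py.  Flags each comparison with the
EMA signal criterion (lower 95% CI bound > 1 and >= 5 ICSRs) and writes
one forest-table CSV per index drug under results/ror/.

Run:  python analysis/03_disproportionality.py
"""

import subprocess
import sys
from pathlib import Path

import pvsignal as pv
from pvsignal.disproportionality import default_events, panel_to_frame, ror_panel

DATA = Path("scratch/synthetic_db")
OUT = Path("results/ror")
DRUGS = [
    "CAPECITABINE", "FLUOROURACIL", "BEVACIZUMAB",
    "OXALIPLATIN", "IRINOTECAN", "PANITUMUMAB",
]


def main() -> None:
    paths = [DATA / n for n in ("reports.csv", "drugs.csv", "reactions.csv")]
    if not all(p.exists() for p in paths):
        print("generating the synthetic database first ...")
        subprocess.run([sys.executable, "analysis/01_simulate.py"], check=True)
    db = pv.read_database(*paths)
    cmap = pv.load_condition_map()
    events = default_events(cmap)
    OUT.mkdir(parents=True, exist_ok=True)

    for index in ("CAPECITABINE", "FLUOROURACIL"):
        comparators = [d for d in DRUGS if d != index]
        entries = ror_panel(db, index, comparators, events, cmap)
        frame = panel_to_frame(entries)
        name = f"ror_panel_{index.lower()}.csv"
        frame.to_csv(OUT / name, index=False)
        signals = frame[frame.get("signal") == True]  # noqa: E712
        print(f"\n{index}: {len(frame)} comparisons, "
              f"{len(signals)} signals of disproportionate reporting -> {OUT / name}")
        for _, row in signals.iterrows():
            print(f"  {row['event']:<24} vs {row['comparator']:<13} "
                  f"ROR {row['ror']:.4f} "
                  f"(95% CI {row['ci_low']:.4f}-{row['ci_high']:.4f}) "
                  f"{row['stars']}")


if __name__ == "__main__":
    main()
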