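# pvsignal

Descriptive and disproportionality analysis of spontaneous adverse-event
report databases, built around the question of fluoropyrimidine
cardiotoxicity: how often are myocardial infarction, heart failure,
cardiomyopathy and arrhythmias reported for capecitabine, how do those
reports end, and is cardiac reporting disproportionate relative to the
other drugs used in colorectal cancer (5-fluorouracil, bevacizumab,
oxaliplatin, irinotecan, panitumumab)?

It is written for pharmacovigilance analysts and biostatisticians who
work with Individual Case Safety Report (ICSR) line listings — the kind
of aggregate extract produced by EudraVigilance, FAERS or VigiBase —
and who need the standard case/non-case toolkit behind a tested,
scriptable API rather than a spreadsheet.

## What it computes

An **ADR** is operationalised as one deduplicated (report, MedDRA
preferred term) pair; an **ICSR** is one report.  Cardiotoxicity is
defined by a 26-term PT map partitioned into four conditions
(8 arrhythmia, 7 heart-failure, 4 cardiomyopathy and 7
myocardial-infarction terms).

Descriptive layer: report characteristics (age / sex / origin /
reporter), the ADR-per-ICSR ratio, seriousness structure, the
distribution of ADRs over the 27 System Organ Classes, outcome profiles
per condition (favourable = recovered/resolved or recovering/resolving;
unfavourable = not recovered or resolved with sequelae; fatal; unknown)
and top-PT rankings.

Disproportionality layer: for an index drug against a comparator, ADR
pairs are split by event membership into the 2×2 table (a, b; c, d) and
the **reporting odds ratio** is

    ROR = (a·d) / (b·c),    SE(log ROR) = √(1/a + 1/b + 1/c + 1/d)

with Woolf (log-method) confidence limits
`exp(log ROR ± z₁₋α/₂ · SE)` and a two-sided normal p-value.  Zero
cells take the Haldane–Anscombe +0.5 correction.  A **signal of
disproportionate reporting** follows the EMA rule: lower 95% CI bound
strictly above 1 with at least 5 supporting ICSRs.

Because the raw EudraVigilance line listings are not redistributable, a
seeded synthetic generator emulates them (per-drug report volumes,
demographic marginals, ≈2 reaction terms per report, per-drug PT
probabilities with controllable enrichment), and a fully deterministic
study-shaped database realises the published capecitabine aggregates
exactly for regression testing.

## Worked example

```python
import pvsignal as pv
from pvsignal.disproportionality import ContingencyTable, compute_ror
from pvsignal.synthetic import study_shaped_fixture

db = study_shaped_fixture("full")          # deterministic capecitabine arm
cmap = pv.load_condition_map()             # built-in 26-term PT map

counts = pv.condition_adr_counts(db, "CAPECITABINE", cmap)
print(counts.total_pairs)                  # 1689 cardiac-condition ADRs

mi = pv.outcome_distribution(db, "CAPECITABINE",
                             pv.Condition.MYOCARDIAL_INFARCTION, cmap)
print(mi.groups.share("favourable"), mi.groups.share("fatal"))  # 70.4 2.0

print(pv.adr_icsr_ratio(db, "CAPECITABINE"))                    # 1.97

result = compute_ror(ContingencyTable(a=10, b=90, c=5, d=95, n_icsr_index=10))
print(round(result.ror, 4), round(result.ci_low, 4), result.signal)
# 2.1111 0.6947 False
```

The first block says: of the 1,689 cardiac-condition ADR pairs in the
capecitabine arm, 70.4% of the 864 myocardial-infarction pairs ended
favourably and 2.0% were fatal, with 1.97 reaction terms per report
overall.  The last block is a case/non-case table in which the index
drug has 10 event and 90 non-event pairs against 5 and 95 for the
comparator: the ROR is 2.11, but its lower confidence bound (0.69) does
not clear 1, so no signal is declared.

## Analysis scripts

The `analysis/` drivers run the study pipeline end to end and write
their tables under `results/`:

```sh
python analysis/01_simulate.py          # synthetic six-drug database (scratch/)
python analysis/02_descriptive.py       # characteristics, outcomes, SOC, top PTs
python analysis/03_disproportionality.py  # ROR forest tables + signal flags
```

The same stages are available as a CLI (`pvsignal simulate / describe /
signal / report`) for arbitrary three-table CSV databases.

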