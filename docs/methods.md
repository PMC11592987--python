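# Methods

## Data model and counting units

A spontaneous-report database is three relational CSV tables joined on
`report_id`: `reports.csv` (demographics and reporter metadata),
`drugs.csv` (active substance + role: suspect, interacting or
concomitant) and `reactions.csv` (MedDRA preferred term, System Organ
Class, seriousness flag, outcome).  Parsing is strict: unknown enum
literals, orphan rows and reports without at least one drug and one
reaction are rejected with the offending file, row and column named.
En dashes in age-group labels are normalised to ASCII hyphens on parse;
drug names are uppercased with collapsed whitespace; PT matching is
case- and whitespace-insensitive.

Two counting units coexist, as they do in spontaneous-reporting
practice.  Characteristics tables count **ICSRs** (reports).  The
ADR/ICSR ratio, seriousness, SOC, outcome and contingency tables count
**ADR pairs** — deduplicated (report, PT) pairs, so a term listed twice
on one report counts once.  Deduplication happens at object
construction, making every downstream tally consistent by
construction.  Seriousness is carried per reaction, and outcome
denominators are ADR pairs, not reports; both are conventions chosen
here because the aggregate tables they reproduce are pair-level.

Duplicate report versions (follow-ups) are assumed already collapsed
upstream; the model enforces report-id uniqueness but performs no
record linkage.

## Condition map

Cardiotoxicity is operationalised as four conditions defined by a fixed
26-PT map (8 arrhythmia, 7 heart-failure, 4 cardiomyopathy, 7
myocardial-infarction terms) shipped as `data/condition_map.csv`.  The
map is reproduced verbatim from its source, including capitalisation
quirks ("Cardiac Tamponade", "Cardiac Hypertrophy") and its editorial
choices: the PT "Heart failure" itself is absent and "Coronary artery
disease" sits under heart failure.  No correction or MedDRA hierarchy
expansion (HLT/HLGT/SMQ) is attempted: the map is the definition, and
terms outside it belong to no condition.  User-supplied maps may not
assign one PT to two conditions.

## Percentages and rounding

Displayed shares are exact integer ratios rounded half-up (ties away
from zero) to one decimal, via decimal arithmetic rather than binary
floats; the ADR/ICSR ratio uses two decimals.  This matches how such
tables are conventionally printed and makes count-derived percentages
reproducible to the digit.  Tables with a zero denominator are returned
flagged with a warning (shares reported as 0) rather than raising,
because per-condition panels legitimately hit empty strata.

## Reporting odds ratio

For index drug vs comparator and an event set (a condition's PTs, or a
whole SOC), ADR pairs split into the 2×2 table (a, b; c, d).  Reports
mentioning both drugs contribute to both arms — no exclusion rule is
applied.  The estimator is ROR = ad/bc with the Woolf log-method:
SE = √(1/a+1/b+1/c+1/d), CI = exp(log ROR ± z·SE), two-sided normal
p-value for log ROR / SE.  When any raw cell is zero the
Haldane–Anscombe correction adds 0.5 to **all four** cells and the
result is flagged `corrected`; with the correction disabled a zero cell
raises instead.  Estimates are kept at full precision internally —
rounding the CI bounds to 4 decimals would break the exchange symmetry
(swap arms ⇒ ROR → 1/ROR, CI bounds swap and invert) that the tests
verify — and are rounded to the conventional 4 decimals only in table
output.

The signal rule is the EMA criterion: `ci_low > 1` (strict) **and** at
least 5 distinct index-drug reports containing an event term.  The
cells a–d count pairs (a report-level unit is available behind a flag),
but the ≥5 threshold always counts ICSRs; both counts travel on the
result.  Significance stars follow the figure-caption convention
(\* p < 0.05, \*\* p ≤ 0.01, \*\*\* p ≤ 0.001, \*\*\*\* p ≤ 0.0001).
Panels are pairwise drug-vs-drug (not drug-vs-rest-of-database), with
per-cell failures recorded on the panel row rather than aborting the
run.  No Bayesian measures, PRR, or multiplicity adjustment are
computed.

## Synthetic generator

`GeneratorConfig` describes per-drug report volumes, demographic
marginals, a reaction-count law, a PT catalogue with per-term weights,
per-drug enrichment multipliers, outcome and seriousness models, an
optional co-mention probability and one seed (single RNG stream, no
global state).  Defaults are the study conditions: the six drugs at
their real report volumes (37,983 capecitabine … 6,950 panitumumab),
reaction counts 1 + Poisson(0.97) giving the observed ≈1.97 terms per
report, demographic marginals taken from the capecitabine
characteristics table, a catalogue whose SOC mix follows the observed
distribution (cardiac ≈3.4%), seriousness 0.934, and per-condition
outcome laws matching the observed splits.

Within a report, PTs are drawn **without replacement** via the Gumbel
top-k trick (equivalent to sequential renormalised draws), honouring
the one-PT-per-report counting rule.  A consequence: marginal per-term
frequencies under multi-term reports deviate slightly from the
configured weights by design, so the goodness-of-fit test of the
generator targets the per-draw law (single-reaction reports), where the
draws are exactly multinomial.

`embed_disproportionality` plants a known effect analytically: scaling
the index drug's event-term weights by m (before renormalisation)
multiplies its event *odds* by exactly m, so the multiplier solving
odds_index = ρ·odds_comparator is closed-form.  Targets that would push
the index event probability above 0.99 (leaving <1% mass for non-event
terms) are rejected as infeasible.  Because the measured ROR is
pair-level while the embedded odds are per-draw, recovery is exact in
expectation up to the (negligible, with small event masses) depletion
induced by within-report no-replacement sampling; the recovery tests
bound the deviation by 3·SE.

What the generator does **not** emulate: reporting dynamics over
calendar time, dose, drug–drug interaction structure, correlated
demographics, reporter-dependent term choice, or duplicate/follow-up
reports.  Co-mentions default to off (real co-reporting rates are
unknown) and, when enabled, attach a uniformly chosen second drug as
concomitant.  Tests passing on these databases therefore validate the
counting and estimation machinery, not the realism of any particular
epidemiological claim.

## Study-shaped fixture

`study_shaped_fixture("full")` assembles — by direct count assembly,
not sampling, hence seedless and bit-reproducible — a capecitabine arm
whose aggregates equal the published figures exactly: 37,983 reports;
74,827 ADR pairs (so the ratio prints 1.97), 69,889 of them serious
(93.4%); exact age/sex/origin/reporter marginals; 2,544 cardiac-SOC
pairs (3.4%); and 1,689 condition pairs (864 MI / 330 HF / 241
cardiomyopathy / 254 arrhythmia) with the published favourable and
fatal counts per condition.  Published totals pin only part of the
structure; the free remainder is fixed by documented conventions:
favourable pairs split evenly between recovered and recovering;
the non-favourable, non-fatal remainder goes half to unknown, one tenth
to sequelae, the rest to not-recovered; per-PT counts below each
condition's published leaders are chosen to preserve the published
ranking (Kounis syndrome = 5, which is reported); non-cardiac pairs are
spread over a synthetic filler vocabulary so each SOC hits its printed
share, with the rounding residue absorbed by the largest
general-disorders term.  Demographic dimensions are assigned in blocks,
so marginals are exact but the joint distribution is degenerate — the
fixture validates marginal tallies, not cross-tabulations.
`study_shaped_fixture("cardiac")` is a 1,689-report miniature carrying
only the condition pairs, for condition-level checks where the full arm
is unnecessary.

## Numerical and testing choices

Normal quantiles and tail probabilities come from scipy; CSV I/O from
pandas; everything contribution-specific (tallies, estimator, signal
rule, generator, fixture) is implemented here and cross-checked in the
test suite against independent pure-Python brute-force scans and a
hand-evaluated Woolf oracle.  Null CI coverage is checked over 1,000
seeded binomial tables (500 reports per arm, event probability 0.1) and
required to land in 95% ± 2%; embedded-ROR recovery is checked for
ρ ∈ {0.5, 1, 2, 4} at 5,000 reports per arm within 3·SE on the log
scale.  The brute-force equivalence battery uses 100 seeded six-drug
databases of ≈430 reports each — large enough to populate every
stratum, small enough to keep the whole suite under a minute.  Analysis
drivers run the generator at 5% of the real volumes (~10,700 reports)
for the same reason; the full-volume default remains available.

## Known limitations

Published ROR panels cannot be recomputed because their 2×2 cell counts
were never printed; the estimator is validated by its properties
instead, and panel reproduction on synthetic data is structural.  The
condition map is a fixed 26-term subset, not a full MedDRA SMQ; drug
names are matched literally (no synonym dictionary); and no
calendar-time or exposure denominators exist anywhere in the model, so
nothing here estimates incidence — only reporting disproportion.
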