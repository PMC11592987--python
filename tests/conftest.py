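import dataclasses

import pytest

import pvsignal as pv
from pvsignal.synthetic import default_config, generate_database, study_shaped_fixture

TINY_REPORTS = """\
report_id,age_group,sex,origin,reporter
R1,18-64Y,F,EEA,HP
R2,65-85Y,M,NON-EEA,NON-HP
R3,NS,NS,NS,NS
"""

TINY_DRUGS = """\
report_id,drug_name,role
R1,CAPECITABINE,SUSPECT
R1,OXALIPLATIN,CONCOMITANT
R2,CAPECITABINE,SUSPECT
R3,FLUOROURACIL,INTERACTING
"""

TINY_REACTIONS = """\
report_id,pt,soc,serious,outcome
R1,Angina pectoris,Cardiac disorders,TRUE,R_RS
R1,Diarrhoea,Gastrointestinal disorders,FALSE,UNKNOWN
R2,Atrial fibrillation,Cardiac disorders,TRUE,FATAL
R2,Nausea,Gastrointestinal disorders,FALSE,RG_RSG
R3,Cardiotoxicity,Cardiac disorders,TRUE,NR_NRS
"""


@pytest.fixture
def tiny_csvs(tmp_path):
    """The 3-report / 5-reaction hand-written database on disk."""
    paths = (
        tmp_path / "reports.csv",
        tmp_path / "drugs.csv",
        tmp_path / "reactions.csv",
    )
    for path, text in zip(paths, (TINY_REPORTS, TINY_DRUGS, TINY_REACTIONS)):
        path.write_text(text)
    return paths


@pytest.fixture(scope="session")
def cmap():
    return pv.load_condition_map()


@pytest.fixture(scope="session")
def full_fixture():
    """The deterministic capecitabine arm at its published size."""
    return study_shaped_fixture("full")


@pytest.fixture(scope="session")
def cardiac_fixture():
    return study_shaped_fixture("cardiac")


def make_small_db(seed: int, scale: float = 0.002) -> pv.Database:
    """A random six-drug database of a few hundred reports.

    Co-mentions are switched on so that some reports carry a second
    (concomitant) drug and the subset/contingency logic is exercised.
    """
    cfg = default_config(scale=scale, seed=seed)
    cfg = dataclasses.replace(cfg, co_mention_probability=0.15)
    return generate_database(cfg)


@pytest.fixture
def small_db():
    return make_small_db(seed=7)


@pytest.fixture(scope="session")
def two_arm_config():
    """Two drugs at 5,000 reports each, shared default term catalogue."""
    cfg = default_config(seed=0)
    return dataclasses.replace(
        cfg,
        drugs=[
            pv.synthetic.DrugVolume("INDEXDRUG", 5000),
            pv.synthetic.DrugVolume("COMPDRUG", 5000),
        ],
    )


# ------------------------------------------------------------------
# independent brute-force oracles (pure Python, no pandas paths)
# ------------------------------------------------------------------


def brute_subset_ids(db, drug_name, roles):
    from pvsignal.icsr import Role, normalize_drug_name

    name = normalize_drug_name(drug_name)
    role_set = {Role(r) if not isinstance(r, Role) else r for r in roles}
    out = []
    for report in db.reports:
        for entry in report.drugs:
            if entry.drug_name == name and entry.role in role_set:
                out.append(report.report_id)
                break
    return out


def brute_pairs(db, drug_name):
    """(report_id, pt_norm, soc, serious, outcome) tuples, deduped per report."""
    ids = set(brute_subset_ids(db, drug_name, list(pv.Role)))
    pairs = []
    for report in db.reports:
        if report.report_id not in ids:
            continue
        seen = set()
        for rx in report.reactions:
            if rx.pt_norm in seen:
                continue
            seen.add(rx.pt_norm)
            pairs.append(
                (report.report_id, rx.pt_norm, rx.soc, rx.serious, rx.outcome)
            )
    return pairs


def brute_condition_tally(db, drug_name, cmap):
    counts = {c: 0 for c in pv.Condition}
    for _, pt, _, _, _ in brute_pairs(db, drug_name):
        c = cmap.classify(pt)
        if c is not None:
            counts[c] += 1
    return counts


def brute_contingency(db, index, comparator, event_pts):
    from pvsignal.icsr import normalize_pt

    pts = {normalize_pt(p) for p in event_pts}
    def arm(drug):
        a = b = 0
        reports_with_event = set()
        for rid, pt, _, _, _ in brute_pairs(db, drug):
            if pt in pts:
                a += 1
                reports_with_event.add(rid)
            else:
                b += 1
        return a, b, len(reports_with_event)

    a, b, n = arm(index)
    c, d, _ = arm(comparator)
    return a, b, c, d, n
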