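"""Seeded synthetic ICSR databases with the structure the analyses assume.

Two generators live here:

* :func:`generate_database` draws a random database from a
  :class:`GeneratorConfig`: per-drug report volumes, demographic
  marginals, a shifted-Poisson reaction count per report (minimum one),
  and PTs drawn without replacement from per-drug, enrichment-adjusted
  term probabilities.  :func:`embed_disproportionality` solves the odds
  equation analytically so that a chosen drug/event combination has a
  known true reporting odds ratio, enabling recovery tests.

* :func:`study_shaped_fixture` assembles — by direct count assembly, not
  sampling — a fully deterministic capecitabine database whose condition
  totals, outcome splits, demographic marginals, seriousness and SOC
  structure equal the published EudraVigilance aggregates exactly
  (37,983 reports; 74,827 ADR pairs; 1,689 cardiac-condition pairs).

The default configuration mirrors the study conditions: the six colon
cancer drugs at their real report volumes, ~1.97 reaction terms per
report, demographic marginals from the capecitabine characteristics
table, and a term catalogue whose SOC mix follows the published
distribution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .conditions import Condition, ConditionMap, load_condition_map
from .descriptive import round_half_up
from .icsr import (
    AgeGroup,
    Database,
    DrugEntry,
    ICSR,
    Origin,
    Outcome,
    Reaction,
    Reporter,
    Role,
    Sex,
    ValidationError,
    normalize_drug_name,
    normalize_pt,
)

__all__ = [
    "InfeasibleTargetError",
    "PTSpec",
    "DrugVolume",
    "GeneratorConfig",
    "default_config",
    "default_pt_catalog",
    "drug_pt_weights",
    "event_probability",
    "generate_database",
    "embed_disproportionality",
    "study_shaped_fixture",
    "FIXTURE_TOTALS",
]


class InfeasibleTargetError(ValueError):
    """An embedded odds target would push a probability outside (0, 1)."""


# ---------------------------------------------------------------------------
# published aggregates used by the fixture and the default configuration
# ---------------------------------------------------------------------------

#: Reports per drug in the source extraction (capecitabine and comparators).
STUDY_DRUG_VOLUMES: dict[str, int] = {
    "CAPECITABINE": 37_983,
    "FLUOROURACIL": 36_683,
    "BEVACIZUMAB": 57_757,
    "OXALIPLATIN": 56_460,
    "IRINOTECAN": 17_728,
    "PANITUMUMAB": 6_950,
}

_N_REPORTS = 37_983
# 74,827 / 37,983 = 1.9700 -> printed ADR/ICSR ratio 1.97
_N_PAIRS = 74_827
# 69,889 / 74,827 = 93.40% serious
_N_SERIOUS = 69_889
# 2,544 / 74,827 = 3.40% of pairs in the cardiac SOC
_N_CARDIAC_SOC = 2_544

_AGE_COUNTS: dict[AgeGroup, int] = {
    AgeGroup.NS: 7_837,
    AgeGroup.M0_1: 12,
    AgeGroup.M2_2Y: 20,
    AgeGroup.Y3_11: 8,
    AgeGroup.Y12_17: 19,
    AgeGroup.Y18_64: 17_015,
    AgeGroup.Y65_85: 12_654,
    AgeGroup.OVER_85: 418,
}
_SEX_COUNTS: dict[Sex, int] = {Sex.FEMALE: 21_557, Sex.MALE: 14_706, Sex.NS: 1_720}
_ORIGIN_COUNTS: dict[Origin, int] = {
    Origin.EEA: 12_405,
    Origin.NON_EEA: 25_578,
    Origin.NS: 0,
}
_REPORTER_COUNTS: dict[Reporter, int] = {
    Reporter.HP: 33_602,
    Reporter.NON_HP: 4_333,
    Reporter.NS: 48,
}

#: Per-PT ADR-pair counts of the four cardiotoxicity conditions in the
#: capecitabine arm.  The leading counts of each condition are published
#: figures; the tail completes the published condition totals
#: (864 / 330 / 241 / 254) while preserving the published ranking.
CONDITION_PT_COUNTS: dict[Condition, list[tuple[str, int]]] = {
    Condition.MYOCARDIAL_INFARCTION: [
        ("Angina pectoris", 271),
        ("Arterio-spasm coronary", 258),
        ("Acute myocardial infarction", 156),
        ("Acute coronary syndrome", 105),
        ("Angina unstable", 45),
        ("Prinzmetal angina", 24),
        ("Kounis syndrome", 5),
    ],
    Condition.HEART_FAILURE: [
        ("Cardiac arrest", 185),
        ("Cardiogenic shock", 40),
        ("Left ventricular dysfunction", 30),
        ("Coronary artery disease", 25),
        ("Cardiac Tamponade", 20),
        ("Cardiac ventricular disorder", 18),
        ("Right ventricular dysfunction", 12),
    ],
    Condition.CARDIOMYOPATHY: [
        ("Cardiotoxicity", 173),
        ("Cardiomyopathy", 30),
        ("Ischaemic cardiomyopathy", 22),
        ("Cardiac Hypertrophy", 16),
    ],
    Condition.ARRHYTHMIAS: [
        ("Atrial fibrillation", 128),
        ("Arrhythmia", 30),
        ("Atrioventricular block", 24),
        ("Bradycardia", 22),
        ("Supraventricular tachycardia", 18),
        ("Atrial flutter", 14),
        ("Atrial tachycardia", 12),
        ("Arrhythmia supraventricular", 6),
    ],
}

#: (total, favourable, fatal) ADR pairs per condition, capecitabine arm.
CONDITION_OUTCOME_SPLITS: dict[Condition, tuple[int, int, int]] = {
    Condition.MYOCARDIAL_INFARCTION: (864, 608, 17),
    Condition.HEART_FAILURE: (330, 142, 93),
    Condition.CARDIOMYOPATHY: (241, 116, 16),
    Condition.ARRHYTHMIAS: (254, 105, 37),
}

FIXTURE_TOTALS = {
    "reports": _N_REPORTS,
    "pairs": _N_PAIRS,
    "serious": _N_SERIOUS,
    "cardiac_soc_pairs": _N_CARDIAC_SOC,
    "condition_pairs": 1_689,
}

CARDIAC_SOC = "Cardiac disorders"

#: SOC shares (percent of ADR pairs) of the capecitabine arm.
_SOC_PCT: dict[str, float] = {
    "Blood and lymphatic system disorders": 11.7,
    "Congenital, familial and genetic disorders": 0.3,
    "Ear and labyrinth disorders": 0.3,
    "Endocrine disorders": 0.2,
    "Eye disorders": 0.9,
    "Gastrointestinal disorders": 15.0,
    "General disorders and administration site conditions": 13.7,
    "Hepatobiliary disorders": 2.5,
    "Immune system disorders": 0.6,
    "Infections and infestations": 3.8,
    "Injury, poisoning and procedural complications": 3.6,
    "Investigations": 7.4,
    "Metabolism and nutrition disorders": 3.9,
    "Musculoskeletal and connective tissue disorders": 2.2,
    "Neoplasms benign, malignant and unspecified (including cysts and polyps)": 5.3,
    "Nervous system disorders": 6.1,
    "Pregnancy, puerperium and perinatal conditions": 0.0,
    "Product issues": 0.1,
    "Psychiatric disorders": 1.1,
    "Renal and urinary disorders": 1.9,
    "Reproductive system and breast disorders": 0.4,
    "Respiratory, thoracic and mediastinal disorders": 3.6,
    "Skin and subcutaneous tissue disorders": 9.0,
    "Social circumstances": 0.1,
    "Surgical and medical procedures": 0.3,
    "Vascular disorders": 2.5,
}

#: Synthetic filler vocabulary: plausible PTs for each non-condition slot.
_FILLER_PTS: dict[str, list[str]] = {
    CARDIAC_SOC: ["Tachycardia", "Palpitations", "Pericardial effusion"],
    "Blood and lymphatic system disorders": [
        "Anaemia", "Neutropenia", "Thrombocytopenia",
    ],
    "Congenital, familial and genetic disorders": [
        "Dihydropyrimidine dehydrogenase deficiency",
    ],
    "Ear and labyrinth disorders": ["Vertigo", "Tinnitus"],
    "Endocrine disorders": ["Hypothyroidism"],
    "Eye disorders": ["Lacrimation increased", "Vision blurred"],
    "Gastrointestinal disorders": [
        "Diarrhoea", "Nausea", "Vomiting", "Stomatitis",
    ],
    "General disorders and administration site conditions": [
        "Fatigue", "Pyrexia", "Asthenia", "Mucosal inflammation",
    ],
    "Hepatobiliary disorders": ["Hepatotoxicity", "Hyperbilirubinaemia"],
    "Immune system disorders": ["Hypersensitivity", "Anaphylactic reaction"],
    "Infections and infestations": ["Sepsis", "Pneumonia"],
    "Injury, poisoning and procedural complications": [
        "Overdose", "Off label use",
    ],
    "Investigations": [
        "Blood pressure increased", "Weight decreased",
        "Ejection fraction decreased",
    ],
    "Metabolism and nutrition disorders": ["Decreased appetite", "Dehydration"],
    "Musculoskeletal and connective tissue disorders": ["Myalgia", "Arthralgia"],
    "Neoplasms benign, malignant and unspecified (including cysts and polyps)": [
        "Neoplasm progression", "Neoplasm malignant",
    ],
    "Nervous system disorders": [
        "Neuropathy peripheral", "Headache", "Dysgeusia",
    ],
    "Pregnancy, puerperium and perinatal conditions": ["Abortion spontaneous"],
    "Product issues": ["Product dose omission issue"],
    "Psychiatric disorders": ["Insomnia", "Anxiety"],
    "Renal and urinary disorders": ["Acute kidney injury", "Proteinuria"],
    "Reproductive system and breast disorders": ["Erectile dysfunction"],
    "Respiratory, thoracic and mediastinal disorders": ["Dyspnoea", "Epistaxis"],
    "Skin and subcutaneous tissue disorders": [
        "Palmar-plantar erythrodysaesthesia syndrome", "Rash", "Alopecia",
    ],
    "Social circumstances": [
        "Loss of personal independence in daily activities",
    ],
    "Surgical and medical procedures": ["Hospitalisation"],
    "Vascular disorders": ["Hypertension", "Embolism"],
}

_OUTCOME_ORDER = [
    Outcome.RECOVERED_RESOLVED,
    Outcome.RECOVERING_RESOLVING,
    Outcome.NOT_RECOVERED,
    Outcome.SEQUELAE,
    Outcome.FATAL,
    Outcome.UNKNOWN,
]


def _condition_outcome_counts(total: int, favourable: int, fatal: int) -> dict[Outcome, int]:
    """Six-category counts honouring the published favourable/fatal totals.

    The published figures pin the favourable and fatal counts only; the
    split of favourable pairs between recovered and recovering, and of
    the remainder between not-recovered, sequelae and unknown, is a
    deterministic convention of this package.
    """
    remainder = total - favourable - fatal
    if remainder < 0:
        raise ValueError("favourable + fatal exceed the condition total")
    unknown = remainder // 2
    sequelae = remainder // 10
    return {
        Outcome.RECOVERED_RESOLVED: favourable - favourable // 2,
        Outcome.RECOVERING_RESOLVING: favourable // 2,
        Outcome.NOT_RECOVERED: remainder - unknown - sequelae,
        Outcome.SEQUELAE: sequelae,
        Outcome.FATAL: fatal,
        Outcome.UNKNOWN: unknown,
    }


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PTSpec:
    """One catalogue term: PT, its SOC, and its base per-draw weight."""

    pt: str
    soc: str
    weight: float


@dataclass(frozen=True)
class DrugVolume:
    name: str
    n_reports: int


@dataclass
class GeneratorConfig:
    """All knobs of the random generator; one seed, no global state.

    ``enrichment`` entries are ``(drug, target, multiplier)`` where the
    target is a PT or a condition label; the multiplier scales the
    targeted terms' weights before per-drug renormalisation, which
    multiplies the event *odds* by exactly that factor.
    """

    drugs: list[DrugVolume]
    pt_catalog: list[PTSpec]
    reactions_mean: float = 1.97
    enrichment: list[tuple[str, str, float]] = field(default_factory=list)
    demographics: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome_model: dict[str, dict[str, float]] = field(default_factory=dict)
    serious_probability: dict[str, float] = field(default_factory=dict)
    co_mention_probability: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.drugs:
            raise ValidationError("config needs at least one drug")
        for dv in self.drugs:
            if dv.n_reports <= 0:
                raise ValidationError(f"n_reports must be > 0 for {dv.name!r}")
        if self.reactions_mean < 1:
            raise ValidationError("reactions_mean must be >= 1")
        if not self.pt_catalog:
            raise ValidationError("pt_catalog must be non-empty")
        for spec in self.pt_catalog:
            if not 0 <= spec.weight <= 1:
                raise ValidationError(
                    f"weight for {spec.pt!r} outside [0, 1]: {spec.weight}"
                )
        for _, _, mult in self.enrichment:
            if mult <= 0:
                raise ValidationError("enrichment multipliers must be > 0")
        for dim, marginal in self.demographics.items():
            total = sum(marginal.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"demographic marginal {dim!r} sums to {total}, not 1"
                )
            if any(p < 0 for p in marginal.values()):
                raise ValidationError(f"negative probability in {dim!r}")
        for cls, dist in self.outcome_model.items():
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"outcome model {cls!r} sums to {total}, not 1"
                )
        for cls, p in self.serious_probability.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"serious probability {cls!r} outside [0,1]")
        if not 0 <= self.co_mention_probability <= 1:
            raise ValidationError("co_mention_probability outside [0, 1]")


def default_pt_catalog() -> list[PTSpec]:
    """Condition PTs plus SOC fillers, weighted like the capecitabine arm."""
    specs: list[PTSpec] = []
    for condition, pt_counts in CONDITION_PT_COUNTS.items():
        for pt, count in pt_counts:
            specs.append(PTSpec(pt, CARDIAC_SOC, count / _N_PAIRS))
    cardiac_filler = _N_CARDIAC_SOC - FIXTURE_TOTALS["condition_pairs"]
    for pt in _FILLER_PTS[CARDIAC_SOC]:
        specs.append(
            PTSpec(pt, CARDIAC_SOC, cardiac_filler / len(_FILLER_PTS[CARDIAC_SOC]) / _N_PAIRS)
        )
    for soc, pct in _SOC_PCT.items():
        pts = _FILLER_PTS[soc]
        for pt in pts:
            specs.append(PTSpec(pt, soc, pct / 100 / len(pts)))
    return specs


def _count_marginal(counts: dict) -> dict[str, float]:
    total = sum(counts.values())
    return {k.value: v / total for k, v in counts.items()}


def default_outcome_model() -> dict[str, dict[str, float]]:
    model: dict[str, dict[str, float]] = {}
    for condition, (total, fav, fatal) in CONDITION_OUTCOME_SPLITS.items():
        counts = _condition_outcome_counts(total, fav, fatal)
        model[condition.value] = {o.value: n / total for o, n in counts.items()}
    model["other"] = {
        Outcome.RECOVERED_RESOLVED.value: 0.35,
        Outcome.RECOVERING_RESOLVING.value: 0.10,
        Outcome.NOT_RECOVERED.value: 0.20,
        Outcome.SEQUELAE.value: 0.02,
        Outcome.FATAL.value: 0.05,
        Outcome.UNKNOWN.value: 0.28,
    }
    return model


def default_config(scale: float = 1.0, seed: int = 0) -> GeneratorConfig:
    """The study conditions: six drugs at their real report volumes.

    ``scale`` multiplies every drug's volume (minimum one report) for
    smaller runs; it changes nothing else.
    """
    drugs = [
        DrugVolume(name, max(1, int(round(n * scale))))
        for name, n in STUDY_DRUG_VOLUMES.items()
    ]
    serious = {c.value: 0.934 for c in Condition}
    serious["other"] = 0.934
    return GeneratorConfig(
        drugs=drugs,
        pt_catalog=default_pt_catalog(),
        reactions_mean=1.97,
        demographics={
            "age": _count_marginal(_AGE_COUNTS),
            "sex": _count_marginal(_SEX_COUNTS),
            "origin": _count_marginal(_ORIGIN_COUNTS),
            "reporter": _count_marginal(_REPORTER_COUNTS),
        },
        outcome_model=default_outcome_model(),
        serious_probability=serious,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# weights and embedding
# ---------------------------------------------------------------------------


def _event_mask(
    catalog: list[PTSpec], target: Condition | str, cmap: ConditionMap
) -> np.ndarray:
    """Boolean mask of catalogue terms matched by a PT or condition target."""
    if isinstance(target, Condition):
        pts = cmap.normalized_pts_for(target)
        return np.array([normalize_pt(s.pt) in pts for s in catalog])
    try:
        condition = Condition(str(target).strip().lower())
    except ValueError:
        key = normalize_pt(str(target))
        return np.array([normalize_pt(s.pt) == key for s in catalog])
    pts = cmap.normalized_pts_for(condition)
    return np.array([normalize_pt(s.pt) in pts for s in catalog])


def drug_pt_weights(
    config: GeneratorConfig, drug: str, cmap: ConditionMap | None = None
) -> np.ndarray:
    """Per-draw term probabilities for one drug after enrichment."""
    if cmap is None:
        cmap = load_condition_map()
    weights = np.array([s.weight for s in config.pt_catalog], dtype=float)
    name = normalize_drug_name(drug)
    for entry_drug, target, mult in config.enrichment:
        if normalize_drug_name(entry_drug) != name:
            continue
        mask = _event_mask(config.pt_catalog, target, cmap)
        if not mask.any():
            raise ValidationError(
                f"enrichment target {target!r} matches no catalogue term"
            )
        weights[mask] *= mult
    total = weights.sum()
    if total <= 0:
        raise ValidationError(f"all-zero term weights for drug {drug!r}")
    return weights / total


def event_probability(
    config: GeneratorConfig, drug: str, event: Condition | str
) -> float:
    """Per-draw probability that one reaction of ``drug`` is an event term."""
    cmap = load_condition_map()
    weights = drug_pt_weights(config, drug, cmap)
    return float(weights[_event_mask(config.pt_catalog, event, cmap)].sum())


def embed_disproportionality(
    config: GeneratorConfig,
    index_drug: str,
    comparator: str,
    event: Condition | str,
    target_ror: float,
) -> GeneratorConfig:
    """Return a config whose index/comparator event odds ratio is ``target_ror``.

    Solved analytically: scaling the index drug's event-term weights by
    ``m`` (before renormalisation) multiplies its event odds by exactly
    ``m``, so ``m = target_ror * odds_comparator / odds_index``.  The
    target is infeasible when the implied event probability leaves too
    little mass (< 1%) for non-event terms.
    """
    if target_ror <= 0:
        raise InfeasibleTargetError("target_ror must be > 0")
    names = {normalize_drug_name(d.name) for d in config.drugs}
    for drug in (index_drug, comparator):
        if normalize_drug_name(drug) not in names:
            raise ValidationError(f"drug {drug!r} not in config")
    q_index = event_probability(config, index_drug, event)
    q_comp = event_probability(config, comparator, event)
    if q_index <= 0 or q_comp <= 0 or q_index >= 1 or q_comp >= 1:
        raise InfeasibleTargetError(
            "event probability must lie strictly inside (0, 1) for both drugs"
        )
    odds_comp = q_comp / (1 - q_comp)
    odds_index = q_index / (1 - q_index)
    multiplier = target_ror * odds_comp / odds_index
    new_odds = multiplier * odds_index
    new_p = new_odds / (1 + new_odds)
    if not 0 < new_p <= 0.99:
        raise InfeasibleTargetError(
            f"target ROR {target_ror} pushes the index event probability to "
            f"{new_p:.4f}; at most 0.99 is allowed"
        )
    label = event.value if isinstance(event, Condition) else str(event)
    return dataclasses.replace(
        config,
        enrichment=[*config.enrichment, (normalize_drug_name(index_drug), label, multiplier)],
    )


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

_DEMOGRAPHIC_ENUMS = {
    "age": AgeGroup,
    "sex": Sex,
    "origin": Origin,
    "reporter": Reporter,
}


def generate_database(config: GeneratorConfig) -> Database:
    """Draw a database from the config; deterministic for a fixed seed.

    Each report draws demographics from the configured marginals, a
    reaction count from 1 + Poisson(mean - 1), and that many distinct
    PTs from the drug's enrichment-adjusted term probabilities (Gumbel
    top-k, equivalent to sequential renormalised draws).  Seriousness
    and outcome are drawn per term class (condition or "other").
    """
    config.validate()
    cmap = load_condition_map()
    rng = np.random.default_rng(config.seed)

    catalog = config.pt_catalog
    n_terms = len(catalog)
    pt_names = [s.pt for s in catalog]
    socs = [s.soc for s in catalog]
    classes = []
    for s in catalog:
        condition = cmap.classify(s.pt)
        classes.append(condition.value if condition else "other")
    class_labels = sorted(set(classes) | {"other"})
    class_idx = np.array([class_labels.index(c) for c in classes])

    serious_p = np.array(
        [config.serious_probability.get(c, 0.934) for c in class_labels]
    )
    outcome_cum = np.zeros((len(class_labels), len(_OUTCOME_ORDER)))
    for ci, cls in enumerate(class_labels):
        dist = config.outcome_model.get(cls) or config.outcome_model.get("other")
        if dist is None:
            dist = {Outcome.UNKNOWN.value: 1.0}
        probs = [dist.get(o.value, 0.0) for o in _OUTCOME_ORDER]
        total = sum(probs)
        outcome_cum[ci] = np.cumsum([p / total for p in probs])

    drug_names = [normalize_drug_name(d.name) for d in config.drugs]
    reports: list[ICSR] = []

    for di, dv in enumerate(config.drugs):
        name = drug_names[di]
        n = dv.n_reports
        weights = drug_pt_weights(config, name, cmap)

        k = 1 + rng.poisson(max(config.reactions_mean - 1.0, 0.0), size=n)
        k = np.minimum(k, n_terms)

        with np.errstate(divide="ignore"):
            log_w = np.log(weights)
        keys = log_w[None, :] + rng.gumbel(size=(n, n_terms))
        order = np.argsort(-keys, axis=1)

        demo: dict[str, np.ndarray] = {}
        for dim, enum_cls in _DEMOGRAPHIC_ENUMS.items():
            marginal = config.demographics.get(dim)
            if marginal is None:
                demo[dim] = np.full(n, "NS")
            else:
                cats = list(marginal.keys())
                probs = np.array(list(marginal.values()), dtype=float)
                demo[dim] = rng.choice(cats, size=n, p=probs / probs.sum())

        if config.co_mention_probability > 0 and len(config.drugs) > 1:
            co_mask = rng.random(n) < config.co_mention_probability
            partners = rng.integers(0, len(config.drugs) - 1, size=n)
        else:
            co_mask = np.zeros(n, dtype=bool)
            partners = np.zeros(n, dtype=int)

        chosen = [order[i, : k[i]] for i in range(n)]
        flat = np.concatenate(chosen) if chosen else np.array([], dtype=int)
        flat_class = class_idx[flat]
        serious_flat = rng.random(flat.size) < serious_p[flat_class]
        u_outcome = rng.random(flat.size)
        cum_rows = outcome_cum[flat_class]
        outcome_flat = (u_outcome[:, None] >= cum_rows).sum(axis=1)
        outcome_flat = np.minimum(outcome_flat, len(_OUTCOME_ORDER) - 1)

        pos = 0
        for i in range(n):
            terms = chosen[i]
            reactions = []
            for t in terms:
                reactions.append(
                    Reaction(
                        pt=pt_names[t],
                        soc=socs[t],
                        serious=bool(serious_flat[pos]),
                        outcome=_OUTCOME_ORDER[outcome_flat[pos]],
                    )
                )
                pos += 1
            drugs = [DrugEntry(name, Role.SUSPECT)]
            if co_mask[i]:
                others = [d for d in drug_names if d != name]
                drugs.append(DrugEntry(others[partners[i] % len(others)], Role.CONCOMITANT))
            reports.append(
                ICSR(
                    report_id=f"{name}-{i:07d}",
                    age_group=demo["age"][i],
                    sex=demo["sex"][i],
                    origin=demo["origin"][i],
                    reporter=demo["reporter"][i],
                    drugs=drugs,
                    reactions=reactions,
                )
            )

    return Database(
        reports=reports,
        provenance={"generator": "pvsignal.synthetic", "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# deterministic study-shaped fixture
# ---------------------------------------------------------------------------


def _filler_pool() -> list[tuple[str, str]]:
    """Flat (pt, soc) list of every non-condition ADR pair, fixed order."""
    pool: list[tuple[str, str]] = []
    cardiac_filler = _N_CARDIAC_SOC - FIXTURE_TOTALS["condition_pairs"]
    counts: dict[tuple[str, str], int] = {}
    per = cardiac_filler // len(_FILLER_PTS[CARDIAC_SOC])
    rem = cardiac_filler - per * len(_FILLER_PTS[CARDIAC_SOC])
    for j, pt in enumerate(_FILLER_PTS[CARDIAC_SOC]):
        counts[(pt, CARDIAC_SOC)] = per + (1 if j < rem else 0)

    target_total = _N_PAIRS - FIXTURE_TOTALS["condition_pairs"] - cardiac_filler
    running = 0
    for soc in sorted(_SOC_PCT):
        soc_count = int(round_half_up(_SOC_PCT[soc] / 100 * _N_PAIRS, 0))
        pts = _FILLER_PTS[soc]
        per = soc_count // len(pts)
        rem = soc_count - per * len(pts)
        for j, pt in enumerate(pts):
            counts[(pt, soc)] = per + (1 if j < rem else 0)
        running += soc_count
    # absorb rounding residue in the largest general-disorder term
    residual = target_total - running
    anchor = ("Fatigue", "General disorders and administration site conditions")
    counts[anchor] += residual
    if counts[anchor] < 0:
        raise RuntimeError("negative filler count after residual adjustment")

    for (pt, soc) in sorted(counts, key=lambda x: (x[1], x[0])):
        pool.extend([(pt, soc)] * counts[(pt, soc)])
    return pool


def _block_assign(counts: dict, n: int) -> list:
    """Deterministic category vector realising exact marginal counts."""
    out = []
    for category, count in counts.items():
        out.extend([category] * count)
    if len(out) != n:
        raise RuntimeError("marginal counts do not sum to the report total")
    return out


def study_shaped_fixture(scale: str = "full") -> Database:
    """Deterministic capecitabine database matching the published aggregates.

    ``scale="full"`` realises the whole arm: 37,983 reports, 74,827 ADR
    pairs (69,889 serious), exact demographic marginals, the published
    SOC mix, and 1,689 cardiac-condition pairs with the published
    per-condition outcome splits.  ``scale="cardiac"`` builds only the
    1,689 condition-pair reports (one pair per report) — sufficient for
    condition-level counts, outcome splits and top-PT rankings, but not
    for demographics, seriousness or SOC shares.

    The construction is direct count assembly (seedless): re-generation
    is bit-identical.
    """
    if scale not in ("full", "cardiac"):
        raise ValueError("scale must be 'full' or 'cardiac'")

    condition_pairs: list[tuple[str, Outcome]] = []
    for condition in (
        Condition.MYOCARDIAL_INFARCTION,
        Condition.HEART_FAILURE,
        Condition.CARDIOMYOPATHY,
        Condition.ARRHYTHMIAS,
    ):
        pts = [pt for pt, count in CONDITION_PT_COUNTS[condition] for _ in range(count)]
        total, fav, fatal = CONDITION_OUTCOME_SPLITS[condition]
        outcome_counts = _condition_outcome_counts(total, fav, fatal)
        outcomes = [o for o in _OUTCOME_ORDER for _ in range(outcome_counts[o])]
        condition_pairs.extend(zip(pts, outcomes))
    n_condition = len(condition_pairs)

    drug = [DrugEntry("CAPECITABINE", Role.SUSPECT)]

    if scale == "cardiac":
        reports = [
            ICSR(
                report_id=f"CAP-{i:05d}",
                age_group=AgeGroup.NS,
                sex=Sex.NS,
                origin=Origin.NS,
                reporter=Reporter.NS,
                drugs=list(drug),
                reactions=[Reaction(pt, CARDIAC_SOC, True, outcome)],
            )
            for i, (pt, outcome) in enumerate(condition_pairs)
        ]
        return Database(reports=reports, provenance={"fixture": "cardiac"})

    pool = _filler_pool()
    n_two = _N_PAIRS - _N_REPORTS  # reports carrying two reaction terms
    queue1 = pool[:_N_REPORTS]
    queue2 = pool[_N_REPORTS:]

    age = _block_assign(_AGE_COUNTS, _N_REPORTS)
    sex = _block_assign(_SEX_COUNTS, _N_REPORTS)
    origin = _block_assign(_ORIGIN_COUNTS, _N_REPORTS)
    reporter = _block_assign(_REPORTER_COUNTS, _N_REPORTS)

    filler_outcome = [_OUTCOME_ORDER[j % 6] for j in range(len(pool))]

    reports = []
    pair_counter = 0
    q2_pos = 0
    for i in range(_N_REPORTS):
        specs: list[tuple[str, str, Outcome]] = []
        if i < n_condition:
            pt, outcome = condition_pairs[i]
            specs.append((pt, CARDIAC_SOC, outcome))
            pt2, soc2 = queue1[i]
            specs.append((pt2, soc2, filler_outcome[i]))
        elif i < n_two:
            pt1, soc1 = queue1[i]
            j = _N_REPORTS + q2_pos
            pt2, soc2 = queue2[q2_pos]
            if pt2 == pt1:
                # find the next differing term and swap it in
                swap = q2_pos + 1
                while queue2[swap][0] == pt1:
                    swap += 1
                queue2[q2_pos], queue2[swap] = queue2[swap], queue2[q2_pos]
                pt2, soc2 = queue2[q2_pos]
            specs.append((pt1, soc1, filler_outcome[i]))
            specs.append((pt2, soc2, filler_outcome[j]))
            q2_pos += 1
        else:
            pt1, soc1 = queue1[i]
            specs.append((pt1, soc1, filler_outcome[i]))

        reactions = []
        for pt, soc, outcome in specs:
            reactions.append(
                Reaction(pt, soc, pair_counter < _N_SERIOUS, outcome)
            )
            pair_counter += 1
        reports.append(
            ICSR(
                report_id=f"CAP-{i:05d}",
                age_group=age[i],
                sex=sex[i],
                origin=origin[i],
                reporter=reporter[i],
                drugs=list(drug),
                reactions=reactions,
            )
        )

    if pair_counter != _N_PAIRS:
        raise RuntimeError(f"assembled {pair_counter} pairs, expected {_N_PAIRS}")
    return Database(reports=reports, provenance={"fixture": "full"})
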