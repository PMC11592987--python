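"""Descriptive tables: characteristics, ratio, seriousness, SOC, outcomes."""

import collections
import dataclasses

import pytest

import pvsignal as pv
from pvsignal.descriptive import (
    EmptySelectionError,
    OUTCOME_GROUPS,
    PercentageTable,
    adr_icsr_ratio,
    characteristics_table,
    outcome_distribution,
    round_half_up,
    seriousness_distribution,
    share_percent,
    soc_distribution,
    top_pts,
)
from pvsignal.icsr import DrugEntry, ICSR, Outcome, Reaction
from pvsignal.synthetic import DrugVolume, default_config, generate_database

from conftest import brute_pairs, make_small_db


def _db(reactions_per_report, sex="NS"):
    reports = []
    for i, reactions in enumerate(reactions_per_report):
        reports.append(
            ICSR(
                report_id=f"T{i}",
                age_group="NS",
                sex=sex,
                origin="NS",
                reporter="NS",
                drugs=[DrugEntry("CAPECITABINE", "SUSPECT")],
                reactions=reactions,
            )
        )
    return pv.Database(reports=reports)


def _rx(pt, soc="Cardiac disorders", serious=True, outcome="UNKNOWN"):
    return Reaction(pt=pt, soc=soc, serious=serious, outcome=outcome)


class TestRounding:
    @pytest.mark.parametrize(
        "value,ndigits,expected",
        [(0.05, 1, 0.1), (0.25, 1, 0.3), (2.675, 2, 2.68), (1.965, 2, 1.97)],
    )
    def test_ties_round_away_from_zero(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected

    def test_share_is_exact_integer_arithmetic(self):
        # 21,557 / 37,983 = 56.754...% -> 56.8
        assert share_percent(21557, 37983) == 56.8
        assert share_percent(17015, 37983) == 44.8
        assert share_percent(1, 800) == 0.1  # 0.125 rounds up at 1 dp


class TestPercentageTable:
    def test_counts_must_sum_to_denominator(self):
        with pytest.raises(ValueError):
            PercentageTable.from_counts({"a": 1, "b": 1}, denominator=3)

    def test_zero_denominator_is_flagged_not_fatal(self):
        with pytest.warns(UserWarning):
            table = PercentageTable.from_counts({"a": 0}, denominator=0)
        assert table.warning is not None
        assert table.share("a") == 0.0

    def test_unrounded_shares_sum_to_100(self):
        table = PercentageTable.from_counts({"a": 1, "b": 1, "c": 1})
        assert sum(r.count for r in table.rows) == table.denominator
        assert abs(sum(100 * r.count / table.denominator for r in table.rows) - 100) < 1e-9


class TestCharacteristics:
    def test_single_female_report(self):
        db = _db([[_rx("Nausea")]], sex="F")
        table = characteristics_table(db, "CAPECITABINE")["sex"]
        assert (table.share("F"), table.share("M"), table.share("NS")) == (100.0, 0.0, 0.0)

    def test_all_categories_present_even_at_zero(self, small_db):
        tables = characteristics_table(small_db, "CAPECITABINE")
        assert [r.label for r in tables["age"].rows] == [
            "NS", "0-1M", "2M-2Y", "3-11Y", "12-17Y", "18-64Y", "65-85Y", "85+",
        ]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_tally(self, seed):
        db = make_small_db(seed)
        tables = characteristics_table(db, "CAPECITABINE")
        sub_ids = {
            rid for rid, *_ in [
                (r.report_id,) for r in db.reports
                if any(d.drug_name == "CAPECITABINE" for d in r.drugs)
            ]
        }
        expected = collections.Counter(
            r.sex.value for r in db.reports if r.report_id in sub_ids
        )
        for row in tables["sex"].rows:
            assert row.count == expected.get(row.label, 0)
        assert tables["sex"].denominator == len(sub_ids)


class TestRatio:
    def test_two_pairs_per_report(self):
        db = _db([[_rx("A"), _rx("B")] for _ in range(10)])
        assert adr_icsr_ratio(db, "CAPECITABINE") == 2.00

    def test_identity_case_one_reaction_each(self):
        db = _db([[_rx("A")] for _ in range(7)])
        assert adr_icsr_ratio(db, "CAPECITABINE") == 1.00

    def test_zero_reports_is_an_error(self, small_db):
        with pytest.raises(EmptySelectionError):
            adr_icsr_ratio(small_db, "PLACEBO")

    def test_sampling_mean_recovered_at_n_10000(self):
        """Shifted-Poisson reactions with mean 2 give a ratio within 3 SE."""
        cfg = dataclasses.replace(
            default_config(seed=42),
            drugs=[DrugVolume("ONLYDRUG", 10_000)],
            reactions_mean=2.0,
        )
        ratio = adr_icsr_ratio(generate_database(cfg), "ONLYDRUG")
        # Var of 1 + Poisson(1) is 1, so SE of the mean is 1/100; PT
        # deduplication can only shave a little off the raw mean.
        assert abs(ratio - 2.0) < 3 * 0.01 + 0.01


class TestSeriousness:
    def test_all_serious(self):
        db = _db([[_rx("A", serious=True)]])
        assert seriousness_distribution(db, "CAPECITABINE").share("serious") == 100.0

    def test_constructed_934_of_1000(self):
        reactions = [
            [_rx(f"PT {i}", serious=(i < 934))] for i in range(1000)
        ]
        table = seriousness_distribution(_db(reactions), "CAPECITABINE")
        assert table.count("serious") == 934
        assert table.share("serious") == 93.4

    def test_empty_selection_is_error(self, small_db):
        with pytest.raises(EmptySelectionError):
            seriousness_distribution(small_db, "PLACEBO")

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force(self, seed):
        db = make_small_db(seed)
        table = seriousness_distribution(db, "OXALIPLATIN")
        serious = sum(1 for *_, s, _ in brute_pairs(db, "OXALIPLATIN") if s)
        assert table.count("serious") == serious


class TestSocDistribution:
    def test_single_soc_is_100_percent(self):
        db = _db([[_rx("A"), _rx("B")]])
        table = soc_distribution(db, "CAPECITABINE")
        assert table.share("Cardiac disorders") == 100.0

    def test_fixture_reproduces_printed_cardiac_share(self, full_fixture):
        table = soc_distribution(full_fixture, "CAPECITABINE")
        assert table.share("Cardiac disorders") == 3.4
        assert table.count("Cardiac disorders") == 2544

    @pytest.mark.parametrize("seed", range(3))
    def test_shares_sum_to_100_and_match_brute_force(self, seed):
        db = make_small_db(seed)
        table = soc_distribution(db, "BEVACIZUMAB")
        # each displayed share carries at most 0.05 rounding error
        assert abs(sum(r.share_percent for r in table.rows) - 100.0) <= 0.05 * len(table.rows)
        expected = collections.Counter(
            soc for _, _, soc, _, _ in brute_pairs(db, "BEVACIZUMAB")
        )
        assert {r.label: r.count for r in table.rows} == dict(expected)
        assert [r.label for r in table.rows] == sorted(expected)


class TestOutcomes:
    def test_groups_partition_the_six_categories(self):
        members = [o for group in OUTCOME_GROUPS.values() for o in group]
        assert sorted(members, key=lambda o: o.value) == sorted(
            Outcome, key=lambda o: o.value
        )

    def test_all_unknown(self, cmap):
        db = _db([[_rx("Angina pectoris", outcome="UNKNOWN")]])
        breakdown = outcome_distribution(
            db, "CAPECITABINE", pv.Condition.MYOCARDIAL_INFARCTION, cmap
        )
        assert breakdown.groups.share("unknown") == 100.0

    def test_zero_condition_pairs_flagged_not_fatal(self, cmap):
        db = _db([[_rx("Nausea", soc="Gastrointestinal disorders")]])
        with pytest.warns(UserWarning):
            breakdown = outcome_distribution(
                db, "CAPECITABINE", pv.Condition.HEART_FAILURE, cmap
            )
        assert breakdown.total == 0

    @pytest.mark.parametrize(
        "condition,favourable,fatal",
        [
            (pv.Condition.MYOCARDIAL_INFARCTION, 70.4, 2.0),
            (pv.Condition.ARRHYTHMIAS, 41.3, 14.6),
            (pv.Condition.HEART_FAILURE, 43.0, 28.2),
            (pv.Condition.CARDIOMYOPATHY, 48.1, 6.6),
        ],
    )
    def test_fixture_reproduces_printed_outcome_shares(
        self, full_fixture, cmap, condition, favourable, fatal
    ):
        breakdown = outcome_distribution(full_fixture, "CAPECITABINE", condition, cmap)
        assert breakdown.groups.share("favourable") == favourable
        assert breakdown.groups.share("fatal") == fatal

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_and_condition_totals(self, seed, cmap):
        db = make_small_db(seed)
        counts = pv.condition_adr_counts(db, "CAPECITABINE", cmap)
        for condition in pv.Condition:
            breakdown = outcome_distribution(db, "CAPECITABINE", condition, cmap)
            brute = collections.Counter(
                outcome
                for _, pt, _, _, outcome in brute_pairs(db, "CAPECITABINE")
                if cmap.classify(pt) is condition
            )
            assert breakdown.outcome_counts == {
                o: brute.get(o, 0) for o in Outcome
            }
            assert breakdown.total == counts.pairs[condition]


class TestTopPts:
    def test_fixture_reproduces_printed_ranking(self, cardiac_fixture, cmap):
        mi = top_pts(
            cardiac_fixture, "CAPECITABINE", pv.Condition.MYOCARDIAL_INFARCTION, cmap, 4
        )
        assert mi == [
            ("Angina pectoris", 271),
            ("Arterio-spasm coronary", 258),
            ("Acute myocardial infarction", 156),
            ("Acute coronary syndrome", 105),
        ]
        hf = top_pts(cardiac_fixture, "CAPECITABINE", pv.Condition.HEART_FAILURE, cmap, 1)
        assert hf == [("Cardiac arrest", 185)]
        arr = top_pts(cardiac_fixture, "CAPECITABINE", pv.Condition.ARRHYTHMIAS, cmap, 1)
        assert arr == [("Atrial fibrillation", 128)]
        cm = top_pts(cardiac_fixture, "CAPECITABINE", pv.Condition.CARDIOMYOPATHY, cmap, 1)
        assert cm == [("Cardiotoxicity", 173)]

    def test_ties_break_alphabetically(self, cmap):
        db = _db([[_rx("Bradycardia")], [_rx("Atrial flutter")]])
        ranked = top_pts(db, "CAPECITABINE", pv.Condition.ARRHYTHMIAS, cmap, 5)
        assert ranked == [("Atrial flutter", 1), ("Bradycardia", 1)]

    def test_k_must_be_positive(self, small_db, cmap):
        with pytest.raises(ValueError):
            top_pts(small_db, "CAPECITABINE", pv.Condition.ARRHYTHMIAS, cmap, 0)
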