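"""Reporting odds ratio, Woolf confidence intervals, EMA signal rule."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pvsignal as pv
from pvsignal.disproportionality import (
    ContingencyTable,
    RORResult,
    SocEvent,
    UndefinedEstimateError,
    assess_signal,
    build_contingency,
    compute_ror,
    default_events,
    panel_to_frame,
    ror_panel,
    significance_stars,
)

from conftest import brute_contingency, make_small_db


def woolf_oracle(a, b, c, d, alpha=0.05):
    """Independent re-derivation of the log-method estimate and CI."""
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    lo = math.exp(math.log(ror) - z * se)
    hi = math.exp(math.log(ror) + z * se)
    p = 2 * stats.norm.sf(abs(math.log(ror)) / se)
    return ror, lo, hi, p


class TestComputeRor:
    def test_hand_oracle_example(self):
        """(10,90,5,95): ROR 19/9 with the published-style 4-decimal CI."""
        result = compute_ror(ContingencyTable(10, 90, 5, 95, 10))
        ror, lo, hi, p = woolf_oracle(10, 90, 5, 95)
        assert result.ror == pytest.approx(ror, rel=1e-12)
        assert pv.descriptive.round_half_up(result.ror, 4) == 2.1111
        assert result.ci_low == pytest.approx(lo, rel=1e-12)
        assert result.ci_high == pytest.approx(hi, rel=1e-12)
        assert result.p_value == pytest.approx(p, abs=1e-12)
        # agreement with the independently tabulated reference values
        assert result.ci_low == pytest.approx(0.6946, abs=1e-3)
        assert result.ci_high == pytest.approx(6.4167, abs=1e-2)

    def test_symmetric_table_is_null(self):
        result = compute_ror(ContingencyTable(10, 10, 10, 10, 10))
        assert result.ror == 1.0
        assert result.p_value == 1.0
        assert result.ci_low < 1 < result.ci_high
        assert not result.signal

    @given(
        a=st.integers(1, 400),
        b=st.integers(1, 400),
        c=st.integers(1, 400),
        d=st.integers(1, 400),
    )
    @settings(max_examples=120, deadline=None)
    def test_exchange_symmetry(self, a, b, c, d):
        """Swapping index and comparator inverts the estimate and CI."""
        fwd = compute_ror(ContingencyTable(a, b, c, d, a))
        rev = compute_ror(ContingencyTable(c, d, a, b, c))
        assert math.log(rev.ror) == pytest.approx(-math.log(fwd.ror), abs=1e-9)
        assert math.log(rev.ci_low) == pytest.approx(-math.log(fwd.ci_high), abs=1e-9)
        assert math.log(rev.ci_high) == pytest.approx(-math.log(fwd.ci_low), abs=1e-9)
        assert rev.p_value == pytest.approx(fwd.p_value, abs=1e-9)

    @given(
        a=st.integers(2, 60),
        b=st.integers(2, 60),
        c=st.integers(2, 60),
        d=st.integers(2, 60),
        k=st.integers(2, 8),
    )
    @settings(max_examples=80, deadline=None)
    def test_scaling_preserves_ror_and_narrows_ci(self, a, b, c, d, k):
        base = compute_ror(ContingencyTable(a, b, c, d, a))
        scaled = compute_ror(ContingencyTable(k * a, k * b, k * c, k * d, k * a))
        assert scaled.ror == pytest.approx(base.ror, rel=1e-12)
        assert scaled.ci_low >= base.ci_low - 1e-9
        assert scaled.ci_high <= base.ci_high + 1e-9

    def test_invariants_on_result(self):
        result = compute_ror(ContingencyTable(17, 300, 9, 350, 15))
        assert result.ci_low <= result.ror <= result.ci_high
        assert 0 <= result.p_value <= 1

    def test_zero_cell_continuity_correction(self):
        result = compute_ror(ContingencyTable(0, 10, 5, 95, 0))
        assert result.corrected
        assert math.isfinite(result.ci_low) and math.isfinite(result.ci_high)
        oracle = woolf_oracle(0.5, 10.5, 5.5, 95.5)
        assert result.ror == pytest.approx(oracle[0], abs=5e-5)

    def test_zero_cell_without_continuity_is_error(self):
        with pytest.raises(UndefinedEstimateError):
            compute_ror(ContingencyTable(0, 10, 5, 95, 0), continuity=False)

    def test_nonzero_table_is_not_corrected(self):
        assert not compute_ror(ContingencyTable(1, 1, 1, 1, 1)).corrected


class TestSignalRule:
    def _result(self, ci_low, n_icsr):
        return RORResult(
            ror=max(ci_low, 1.0) * 2,
            ci_low=ci_low,
            ci_high=ci_low * 10,
            p_value=0.01,
            alpha=0.05,
            table=ContingencyTable(n_icsr, 10, 10, 10, n_icsr),
            corrected=False,
            signal=False,
        )

    def test_reported_signal_values_fire(self):
        # lower bound 4.6623 with 100 supporting reports: a clear signal
        assert assess_signal(self._result(4.6623, 100))

    def test_lower_bound_exactly_one_is_no_signal(self):
        assert not assess_signal(self._result(1.0, 100))

    def test_four_reports_is_no_signal(self):
        assert not assess_signal(self._result(2.0, 4))
        assert assess_signal(self._result(2.0, 5))

    def test_min_icsr_is_configurable(self):
        assert assess_signal(self._result(2.0, 3), min_icsr=3)

    @pytest.mark.parametrize(
        "p,expected",
        [(0.2, ""), (0.049, "*"), (0.01, "**"), (0.001, "***"), (0.0001, "****")],
    )
    def test_significance_stars(self, p, expected):
        assert significance_stars(p) == expected


class TestBuildContingency:
    def test_constructed_counts(self, tiny_csvs):
        db = pv.read_database(*tiny_csvs)
        table = build_contingency(
            db, "CAPECITABINE", "FLUOROURACIL", ["Angina pectoris", "Atrial fibrillation"]
        )
        # CAP: 4 pairs of which 2 events on 2 reports; 5-FU: 1 pair, 0 events
        assert (table.a, table.b, table.c, table.d) == (2, 2, 0, 1)
        assert table.n_icsr_index == 2

    def test_soc_level_event(self, tiny_csvs):
        db = pv.read_database(*tiny_csvs)
        table = build_contingency(
            db, "CAPECITABINE", "FLUOROURACIL", event_soc="Cardiac disorders"
        )
        assert (table.a, table.b, table.c, table.d) == (2, 2, 1, 0)

    def test_absent_index_drug_gives_empty_arm(self, tiny_csvs):
        db = pv.read_database(*tiny_csvs)
        table = build_contingency(db, "PLACEBO", "CAPECITABINE", ["Angina pectoris"])
        assert (table.a, table.b) == (0, 0)

    def test_argument_errors(self, tiny_csvs):
        db = pv.read_database(*tiny_csvs)
        with pytest.raises(ValueError):
            build_contingency(db, "CAPECITABINE", "capecitabine", ["Angina pectoris"])
        with pytest.raises(ValueError):
            build_contingency(db, "CAPECITABINE", "FLUOROURACIL", [])
        with pytest.raises(ValueError):
            build_contingency(db, "CAPECITABINE", "FLUOROURACIL")

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_classification(self, seed, cmap):
        db = make_small_db(seed)
        pts = cmap.normalized_pts_for(pv.Condition.MYOCARDIAL_INFARCTION)
        table = build_contingency(db, "CAPECITABINE", "OXALIPLATIN", pts)
        assert (
            table.a,
            table.b,
            table.c,
            table.d,
            table.n_icsr_index,
        ) == brute_contingency(db, "CAPECITABINE", "OXALIPLATIN", pts)

    def test_report_unit_counts_reports(self, tiny_csvs):
        db = pv.read_database(*tiny_csvs)
        table = build_contingency(
            db,
            "CAPECITABINE",
            "FLUOROURACIL",
            ["Angina pectoris"],
            unit="report",
        )
        # 1 of CAP's 2 reports carries the event
        assert (table.a, table.b) == (1, 1)
        assert table.a + table.b == 2


class TestPanel:
    def test_two_comparators_one_event_gives_two_rows(self, small_db, cmap):
        entries = ror_panel(
            small_db,
            "CAPECITABINE",
            ["OXALIPLATIN", "BEVACIZUMAB"],
            {"soc": SocEvent("Cardiac disorders")},
            cmap,
        )
        assert len(entries) == 2
        assert {e.comparator for e in entries} == {"OXALIPLATIN", "BEVACIZUMAB"}

    def test_index_as_comparator_is_an_argument_error(self, small_db, cmap):
        with pytest.raises(ValueError):
            ror_panel(
                small_db, "CAPECITABINE", ["CAPECITABINE"], default_events(cmap), cmap
            )
        with pytest.raises(ValueError):
            ror_panel(small_db, "CAPECITABINE", [], default_events(cmap), cmap)

    def test_default_events_cover_conditions_and_soc(self, cmap):
        events = default_events(cmap)
        assert set(events) == {c.value for c in pv.Condition} | {"cardiac_disorders_soc"}

    def test_panel_frame_layout(self, small_db, cmap):
        entries = ror_panel(
            small_db, "CAPECITABINE", ["OXALIPLATIN"], default_events(cmap), cmap
        )
        frame = panel_to_frame(entries)
        assert len(frame) == 5
        for col in ("event", "comparator", "ror", "ci_low", "ci_high", "signal", "stars"):
            assert col in frame.columns

    def test_failed_cell_is_reported_not_fatal(self, cmap):
        db = make_small_db(3)
        entries = ror_panel(
            db,
            "CAPECITABINE",
            ["PANITUMUMAB"],
            {"rare": ["Kounis syndrome"]},
            cmap,
            continuity=False,
        )
        assert len(entries) == 1
        entry = entries[0]
        assert (entry.result is None) == (entry.error is not None)


class TestCoverageAndRecovery:
    def test_null_coverage_quick_check(self):
        """Woolf 95% CIs cover the null in roughly 95% of binomial tables."""
        rng = np.random.default_rng(2024)
        n, p, covered, sims = 500, 0.1, 0, 300
        for _ in range(sims):
            a = rng.binomial(n, p)
            c = rng.binomial(n, p)
            if min(a, c) == 0:
                continue
            r = compute_ror(ContingencyTable(a, n - a, c, n - c, a))
            covered += r.ci_low <= 1 <= r.ci_high
        assert 0.90 <= covered / sims <= 1.0
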