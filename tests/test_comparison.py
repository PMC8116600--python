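"""Error taxonomy and exact binomial statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from hvfkit.comparison import (
    FORMAT_INCONSISTENCY,
    MATCH,
    TRUE_ERROR,
    clopper_pearson,
    compare_field,
    compare_grid,
    compare_reports,
    summarize,
)
from hvfkit.data_model import PlotGrid, ValueCell

from conftest import make_report


class TestCompareField:
    @pytest.mark.parametrize("ext,ref,fid,expected", [
        ("x", "x", "name", MATCH),
        ("0.47", "-0.47", "mean_deviation", TRUE_ERROR),  # dropped minus sign
        ("SITA Standard", "SITA Fast", "strategy", TRUE_ERROR),
        ("11-15-1941", "11-16-1941", "date_of_birth", TRUE_ERROR),
        ("06:54", "06:543", "test_duration", TRUE_ERROR),
        ("4.1", "4.7", "pupil_diameter", TRUE_ERROR),
        ("sita standard", "SITA Standard", "strategy", FORMAT_INCONSISTENCY),
        ("SITA  Standard", "SITA Standard", "strategy", FORMAT_INCONSISTENCY),
        ("11/15/1941", "11-15-1941", "date_of_birth", FORMAT_INCONSISTENCY),
        ("-4.50", "-4.5", "mean_deviation", FORMAT_INCONSISTENCY),
        ("-0.47 dB", "-0.47", "mean_deviation", FORMAT_INCONSISTENCY),
    ])
    def test_error_taxonomy(self, ext, ref, fid, expected):
        assert compare_field(ext, ref, fid).outcome == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(min_size=0, max_size=30))
    def test_anything_equals_itself(self, text):
        assert compare_field(text, text, "name").outcome == MATCH

    def test_contracts(self):
        with pytest.raises(KeyError):
            compare_field("a", "b", "not_a_field")
        with pytest.raises(TypeError):
            compare_field(None, "b", "name")


class TestCompareGrid:
    def test_identical_grids_all_match(self):
        rep = make_report(0)
        outcomes = compare_grid(rep.raw, rep.raw)
        assert outcomes and all(o.outcome == MATCH for o in outcomes)

    def test_below_threshold_vs_zero_is_a_true_error(self):
        ref = PlotGrid.empty("RAW").with_cell(4, 7, ValueCell("NUMBER", 0))
        ext = PlotGrid.empty("RAW").with_cell(4, 7, ValueCell("BELOW_THRESHOLD"))
        (outcome,) = compare_grid(ext, ref)
        assert outcome.outcome == TRUE_ERROR
        assert (outcome.extracted, outcome.reference) == ("<0", "0")

    def test_one_outcome_per_nonempty_reference_cell(self):
        rep = make_report(0, pattern="24-2")  # 54 non-empty raw points
        outcomes = compare_grid(PlotGrid.empty("RAW"), rep.raw)
        assert len(outcomes) == 54
        assert all(o.outcome == TRUE_ERROR for o in outcomes)  # all missed

    def test_plot_id_mismatch_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            compare_grid(PlotGrid.empty("RAW"), PlotGrid.empty("TD_VALUE"))


class TestClopperPearson:
    @pytest.mark.parametrize("x,n,lo,hi", [
        (18, 510, 2.1, 5.5),
        (46, 5263, 0.6, 1.2),
        (0, 3453, 0.0, 0.1),
        (8, 510, 0.7, 3.1),
    ])
    def test_published_style_intervals_reproduce(self, x, n, lo, hi):
        low, high = clopper_pearson(x, n, 0.95)
        assert round(100 * low, 1) == lo
        assert round(100 * high, 1) == hi

    def test_boundaries_are_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_contracts(self):
        for bad in [(-1, 10, 0.95), (11, 10, 0.95), (0, 0, 0.95), (1, 10, 1.5)]:
            with pytest.raises(ValueError):
                clopper_pearson(bad[0], bad[1], bad[2])

    def test_agrees_with_cdf_inversion_on_a_sample(self):
        # independent oracle: bisect the binomial tail probabilities
        for x, n in [(0, 7), (3, 20), (18, 510), (46, 200), (200, 200)]:
            lo, hi = clopper_pearson(x, n, 0.95)
            if x > 0:
                assert binom.sf(x - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
            if x < n:
                assert binom.cdf(x, n, hi) == pytest.approx(0.025, abs=1e-9)

    def test_interval_coverage_at_small_p(self):
        rng = np.random.default_rng(20240901)
        p, n = 0.01, 500
        draws = rng.binomial(n, p, size=2000)
        covered = 0
        for x in np.unique(draws):
            lo, hi = clopper_pearson(int(x), n, 0.95)
            covered += int(lo <= p <= hi) * int((draws == x).sum())
        assert covered / 2000 >= 0.94


class TestSummarize:
    def test_thirty_reports_by_seventeen_fields(self):
        groups = [
            [compare_field("v", "v", "name") for _ in range(17)]
            for _ in range(30)
        ]
        s = summarize(groups)
        assert s.total_items == 510
        assert s.aggregate_errors == 0
        assert s.rate == 0.0 and s.ci_low == 0.0

    def test_fault_injection_counts_exactly(self):
        rng = np.random.default_rng(7)
        k = 0
        groups = []
        for _ in range(20):
            rep = []
            for _ in range(17):
                if rng.random() < 0.1:
                    rep.append(compare_field("1", "2", "patient_id"))
                    k += 1
                else:
                    rep.append(compare_field("x", "x", "patient_id"))
            groups.append(rep)
        s = summarize(groups)
        assert s.aggregate_errors == k
        assert s.rate == pytest.approx(100 * k / 340)

    def test_permutation_invariance_of_aggregates(self):
        groups = [
            [compare_field(str(i % 3), "0", "patient_id") for i in range(j + 1)]
            for j in range(5)
        ]
        a = summarize(groups)
        b = summarize(list(reversed(groups)))
        assert (a.aggregate_errors, a.total_items, a.rate,
                a.median, a.q1, a.q3) == \
            (b.aggregate_errors, b.total_items, b.rate, b.median, b.q1, b.q3)

    def test_format_inconsistencies_are_tallied_separately(self):
        groups = [[
            compare_field("sita standard", "SITA Standard", "strategy"),
            compare_field("0.47", "-0.47", "mean_deviation"),
        ]]
        s = summarize(groups)
        assert s.aggregate_errors == 1
        assert s.format_inconsistencies == 1


def test_compare_reports_covers_all_categories():
    rep = make_report(0)
    out = compare_reports(rep, rep)
    assert len(out["metadata"]) == 17
    assert all(o.outcome == MATCH
               for cat in out.values() for o in cat)
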