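"""Association statistics: Fisher exact, odds ratios, correction, Svejgaard."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirassoc import (
    ContingencyTable2x2,
    association_from_counts,
    carrier_association,
    classify_cohort,
    correct_pvalue,
    fisher_exact_two_tailed,
    odds_ratio_woolf,
    svejgaard_combined,
)
from kirassoc.stats import DegenerateTableWarning


def fisher_brute_force(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exact integer enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        pt = math.comb(r1, x) * math.comb(r2, c1 - x)
        if pt * 10**7 <= obs * (10**7 + 1):  # 1e-7 relative tie tolerance
            total += pt
    return total / denom


class TestFisher:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((58, 174, 69, 379), 0.0035),   # CxTx carrier comparison, 2 s.f.
            ((5, 5, 5, 5), 1.0),
            ((3, 1, 1, 3), 34 / 70),
        ],
    )
    def test_reference_values(self, cells, expected):
        p = fisher_exact_two_tailed(ContingencyTable2x2(*cells))
        if expected == 34 / 70:
            assert p == pytest.approx(expected, rel=1e-12)
        else:
            assert float(f"{p:.2g}") == expected

    def test_matches_scipy_convention(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_exact_two_tailed(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            ref = fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_matches_brute_force_on_random_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(fisher_brute_force(a, b, c, d), rel=1e-12, abs=1e-12)

    def test_degenerate_margin_warns_and_returns_one(self):
        with pytest.warns(DegenerateTableWarning):
            assert fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=150, deadline=None)
    def test_symmetry(self, a, b, c, d):
        """p is invariant under swapping groups, outcomes, or both."""
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(
            fisher_exact_two_tailed(ContingencyTable2x2(c, d, a, b)), rel=1e-12
        )
        assert p == pytest.approx(
            fisher_exact_two_tailed(ContingencyTable2x2(b, a, d, c)), rel=1e-12
        )
        assert 0 < p <= 1


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells, expected_or, expected_ci",
        [
            ((146, 86, 244, 204), 1.42, None),
            ((2, 50, 25, 128), 0.20, (0.047, 0.90)),
        ],
    )
    def test_reference_values(self, cells, expected_or, expected_ci):
        or_, lo, hi, haldane = odds_ratio_woolf(ContingencyTable2x2(*cells))
        assert round(or_, 2) == expected_or
        assert not haldane
        if expected_ci:
            assert float(f"{lo:.2g}") == expected_ci[0]
            assert round(hi, 2) == expected_ci[1]

    def test_symmetric_table_gives_unit_or(self):
        for k in (1, 7, 30):
            or_, lo, hi, _ = odds_ratio_woolf(ContingencyTable2x2(k, k, k, k))
            assert or_ == 1.0
            assert lo < 1.0 < hi

    def test_matches_statsmodels_interval(self):
        sm = pytest.importorskip("statsmodels.api")
        t = ContingencyTable2x2(146, 86, 244, 204)
        or_, lo, hi, _ = odds_ratio_woolf(t)
        ref = sm.stats.Table2x2(np.array([[146, 86], [244, 204]]))
        lo_ref, hi_ref = ref.oddsratio_confint(0.05)
        assert or_ == pytest.approx(ref.oddsratio, rel=1e-12)
        assert lo == pytest.approx(lo_ref, rel=1e-4)
        assert hi == pytest.approx(hi_ref, rel=1e-4)

    def test_zero_cell_uses_haldane_and_flags(self):
        or_, lo, hi, haldane = odds_ratio_woolf(ContingencyTable2x2(0, 10, 5, 5))
        assert haldane
        assert or_ == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_opposing_zero_cells_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio_woolf(ContingencyTable2x2(0, 10, 5, 0))

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    @settings(max_examples=150, deadline=None)
    def test_reciprocity(self, a, b, c, d):
        or1, *_ = odds_ratio_woolf(ContingencyTable2x2(a, b, c, d))
        or2, *_ = odds_ratio_woolf(ContingencyTable2x2(b, a, d, c))
        assert or1 * or2 == pytest.approx(1.0, rel=1e-12)


class TestCorrection:
    @pytest.mark.parametrize(
        "p, n, expected",
        [(0.002, 4, 0.008), (0.0012, 9, 0.011), (0.05, 9, 0.36975)],
    )
    def test_reference_values(self, p, n, expected):
        assert round(correct_pvalue(p, n), 5) == pytest.approx(expected, abs=5e-4)

    def test_identity_at_n_one(self):
        for p in (0.0, 0.01, 0.5, 1.0):
            assert correct_pvalue(p, 1) == pytest.approx(p)

    @given(st.floats(1e-6, 1 - 1e-6), st.integers(1, 50))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_p_and_n(self, p, n):
        pc = correct_pvalue(p, n)
        assert pc >= p
        assert correct_pvalue(p, n + 1) > pc or pc == 1.0
        assert 0 <= pc <= 1

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalue(1.5, 4)
        with pytest.raises(ValueError):
            correct_pvalue(0.05, 0)


class TestCarrierAssociation:
    def test_identical_proportions_are_null(self):
        res = association_from_counts("x", 20, 100, 40, 200)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == 1.0

    def test_from_cohort_excludes_untyped(self, sim_cohort_missing):
        res = carrier_association(sim_cohort_missing, "2DL2")
        typed = sim_cohort_missing[~sim_cohort_missing["2DL2"].isna()]
        assert res.table.a + res.table.b == int((typed["group"] == "case").sum())
        assert res.table.c + res.table.d == int((typed["group"] == "control").sum())

    def test_correction_applied_when_configured(self):
        res = association_from_counts("x", 150, 232, 234, 448, correction_n=4)
        assert res.p_corrected == pytest.approx(correct_pvalue(res.p_value, 4))
        assert res.p_corrected >= res.p_value


class TestCalibration:
    def test_ci_coverage_and_type_one_error_under_null(self):
        """2,000 null tables (binomial, n=200/200, carrier prob 0.4): the 95% CI
        covers OR=1 in 95% +/- 2%, and Fisher rejects at most ~5%."""
        rng = np.random.default_rng(2024)
        n = 2000
        cover = reject = 0
        for _ in range(n):
            a = rng.binomial(200, 0.4)
            c = rng.binomial(200, 0.4)
            res = association_from_counts("null", int(a), 200, int(c), 200)
            if res.ci_low <= 1.0 <= res.ci_high:
                cover += 1
            if res.p_value < 0.05:
                reject += 1
        assert cover / n == pytest.approx(0.95, abs=0.02)
        assert reject / n <= 0.05 + 0.01


class TestSvejgaard:
    def test_cross_tab_matches_row_scan(self, sim_cohort):
        classified = classify_cohort(sim_cohort)
        rep = svejgaard_combined(classified, "CxTx", "2DL2")
        for group in ("case", "control"):
            sub = classified[classified["group"] == group]
            manual = {
                "A+B+": int((sub["CxTx"] & (sub["2DL2"] == 1)).sum()),
                "A+B-": int((sub["CxTx"] & (sub["2DL2"] == 0)).sum()),
                "A-B+": int((~sub["CxTx"] & (sub["2DL2"] == 1)).sum()),
                "A-B-": int((~sub["CxTx"] & (sub["2DL2"] == 0)).sum()),
            }
            for cls, count in manual.items():
                assert rep.cross_tab.loc[group, cls] == count
            assert rep.cross_tab.loc[group].sum() == len(sub)

    def test_battery_contains_eight_comparisons_plus_combined(self, sim_cohort):
        classified = classify_cohort(sim_cohort)
        rep = svejgaard_combined(classified, "CxTx", "2DS2")
        assert len(rep.battery) == 8
        assert rep.combined_carrier is not None

    def test_subgroup_comparison_equals_direct_subset_test(self, sim_cohort):
        """'A within B+' must equal running the marginal test on the B+ subset."""
        classified = classify_cohort(sim_cohort)
        rep = svejgaard_combined(classified, "2DS2", "iKIR>aKIR")
        direct = carrier_association(
            classified[classified["iKIR>aKIR"] == True], "2DS2"  # noqa: E712
        )
        sub = rep.battery["2DS2 within iKIR>aKIR+"]
        assert sub.table == direct.table
        assert sub.p_value == pytest.approx(direct.p_value)

    def test_constant_true_factor_b_reduces_to_marginal(self, sim_cohort):
        classified = classify_cohort(sim_cohort).copy()
        classified["always"] = pd.array([True] * len(classified), dtype="boolean")
        rep = svejgaard_combined(classified, "2DL2", "always")
        marginal = carrier_association(classified, "2DL2")
        assert rep.battery["2DL2 marginal"].table == marginal.table
        assert rep.battery["2DL2 within always+"].table == marginal.table
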