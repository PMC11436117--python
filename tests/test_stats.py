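"""Statistical battery: rank-sum, effect sizes, multiplicity, demographics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from specmdd.features import design_columns
from specmdd.stats import (BatteryDesign, anova_oneway_summary,
                           bonferroni_adjust, chi_square_2x2, hedges_g,
                           run_battery, spearman_corr, wilcoxon_ranksum)


class TestWilcoxon:
    def test_exact_enumeration_example(self):
        # all C(6,3)=20 rank splits: {1,2,3} vs {4,5,6} is the most extreme
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.10)

    def test_identical_samples_give_p_one(self):
        _, p = wilcoxon_ranksum([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_matches_scipy_asymptotic_with_continuity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.standard_normal(74)
            y = rng.standard_normal(40) + rng.uniform(-0.5, 0.5)
            _, ours = wilcoxon_ranksum(x, y)
            ref = sps.mannwhitneyu(x, y, use_continuity=True).pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_matches_scipy_exact_on_tiny_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = rng.integers(0, 6, size=5).astype(float)
            y = rng.integers(0, 6, size=4).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            _, ours = wilcoxon_ranksum(x, y)
            if len(np.unique(np.concatenate([x, y]))) == 9:  # tie-free only
                ref = sps.mannwhitneyu(x, y, method="exact").pvalue
                assert ours == pytest.approx(ref, rel=1e-10)

    @given(st.floats(0.1, 5), st.floats(-3, 3))
    def test_invariant_under_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(30)
        y = rng.standard_normal(25) + 0.4
        _, p0 = wilcoxon_ranksum(x, y)
        _, p1 = wilcoxon_ranksum(np.exp(scale * x + shift),
                                 np.exp(scale * y + shift))
        assert p0 == pytest.approx(p1)

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum([], [1.0])


class TestHedgesG:
    def test_identical_groups(self):
        assert hedges_g([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_example(self):
        # d = -1, J = 1 - 3/15 = 0.8 -> g = -0.8
        assert hedges_g([0, 1, 2], [1, 2, 3]) == pytest.approx(-0.8)

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(20), rng.standard_normal(25) + 0.3
        assert hedges_g(x, y) == pytest.approx(-hedges_g(y, x))
        assert hedges_g(3.7 * x, 3.7 * y) == pytest.approx(hedges_g(x, y))

    def test_errors(self):
        with pytest.raises(ValueError):
            hedges_g([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0], [2.0, 2.0])  # zero pooled variance


class TestBonferroni:
    def test_basic_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni_adjust([0.001], 50), [0.05])
        np.testing.assert_allclose(bonferroni_adjust([0.5], 50), [1.0])
        np.testing.assert_allclose(bonferroni_adjust([0.3, 0.01], 2),
                                   [0.6, 0.02])

    def test_identity_at_family_one(self):
        np.testing.assert_allclose(bonferroni_adjust([0.123], 1), [0.123])

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1], 0)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], 1)


def _random_table(rng, n_hc=74, n_mdd=40, effect=None):
    cols = design_columns()
    data = {c: rng.standard_normal(n_hc + n_mdd) for c in cols}
    if effect:
        key, g = effect
        data[key][n_hc:] -= g
    data["group"] = ["HC"] * n_hc + ["MDD"] * n_mdd
    return pd.DataFrame(data)


class TestBattery:
    def test_default_design_is_fifty_tests(self, feature_cohort):
        from specmdd.features import build_feature_table

        table = build_feature_table(feature_cohort, {}, {})
        results = run_battery(table)
        assert len(results) == 50
        assert BatteryDesign().family_size == 50

    def test_factorial_structure_and_ordering(self):
        cells = BatteryDesign().cells()
        banded = [c for c in cells if c[3] is not None]
        aperiodic = [c for c in cells if c[0] == "aperiodic"]
        assert len(banded) == 2 * 2 * 5 * 2 and len(aperiodic) == 2 * 5
        assert cells == sorted(
            cells, key=lambda c: (("psd", "periodic", "aperiodic").index(c[0]),))

    def test_electrode_only_design_is_25(self):
        assert BatteryDesign(spaces=("electrode",)).family_size == 25

    def test_missing_feature_still_counts_toward_family(self):
        rng = np.random.default_rng(0)
        table = _random_table(rng).drop(columns=["source_aperiodic_frontal"])
        results = run_battery(table)
        assert len(results) == 50
        row = [r for r in results if r.key == "source_aperiodic_frontal"][0]
        assert row.degenerate and np.isnan(row.p_raw)
        finite = [r.p_adjusted / r.p_raw for r in results
                  if np.isfinite(r.p_raw) and r.p_adjusted < 1]
        assert all(f == pytest.approx(50) for f in finite)

    def test_familywise_error_controlled_under_null(self):
        """Over simulated null batteries the familywise rejection rate at
        alpha = 0.05 stays at or below the nominal level."""
        rng = np.random.default_rng(5)
        fwer = np.mean([
            any(r.p_adjusted < 0.05 for r in run_battery(_random_table(rng)))
            for _ in range(300)])
        assert fwer <= 0.05 + 0.03

    def test_power_to_flag_unit_effect(self):
        """A single feature carrying a generating g = 1.0 gap must survive
        Bonferroni in well over half of simulated batteries."""
        rng = np.random.default_rng(6)
        key = "electrode_periodic_parietal_theta"
        hits = 0
        for _ in range(100):
            res = run_battery(_random_table(rng, effect=(key, 1.0)))
            row = [r for r in res if r.key == key][0]
            hits += row.p_adjusted < 0.05
        assert hits / 100 > 0.5

    def test_requires_both_groups(self):
        rng = np.random.default_rng(7)
        table = _random_table(rng)
        with pytest.raises(ValueError):
            run_battery(table[table.group == "HC"])


class TestDemographics:
    def test_tai_anova_matches_printed_value(self):
        f, dfb, dfw, p = anova_oneway_summary(74, 31.12, 5.49, 40, 56.15, 6.81)
        assert (dfb, dfw) == (1, 112)
        assert f == pytest.approx(453.0, rel=0.01)
        assert p < 0.001

    def test_summary_anova_agrees_with_raw_data_anova(self):
        """Construct raw samples with exactly the summary moments and compare
        with scipy's raw-data one-way ANOVA."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            n1, n2 = 20, 15
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2)
            m1, s1 = 2.0, 1.3
            m2, s2 = 2.6, 0.9
            x = (x - x.mean()) / x.std(ddof=1) * s1 + m1
            y = (y - y.mean()) / y.std(ddof=1) * s2 + m2
            f_sum = anova_oneway_summary(n1, m1, s1, n2, m2, s2)[0]
            f_raw = sps.f_oneway(x, y).statistic
            assert f_sum == pytest.approx(f_raw, abs=1e-6)

    def test_equal_means_give_zero_f(self):
        f, *_ = anova_oneway_summary(10, 1.0, 0.5, 12, 1.0, 0.7)
        assert f == 0.0

    def test_gender_chi_square_matches_printed_value(self):
        chi2, df, p = chi_square_2x2(35, 39, 10, 30)
        assert df == 1
        assert chi2 == pytest.approx(5.40, abs=0.005)
        assert p == pytest.approx(0.02, abs=0.005)

    def test_proportional_table_gives_zero(self):
        chi2, _, p = chi_square_2x2(10, 20, 20, 40)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_observed_vs_expected_definition(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 50, size=4)
            chi2, _, _ = chi_square_2x2(a, b, c, d)
            ref = sps.chi2_contingency([[a, b], [c, d]],
                                       correction=False).statistic
            assert chi2 == pytest.approx(ref, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)


class TestSpearman:
    def test_monotone_function_gives_unity(self):
        x = np.linspace(0, 5, 20)
        assert spearman_corr(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x ** 3)[0] == pytest.approx(-1.0)

    def test_tied_vectors_match_midrank_hand_computation(self):
        x = [1, 2, 2, 3]
        y = [10, 20, 20, 5]
        # midranks: x -> 1, 2.5, 2.5, 4 ; y -> 2, 3.5, 3.5, 1
        rx, ry = np.array([1, 2.5, 2.5, 4]), np.array([2, 3.5, 3.5, 1])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_corr(x, y)[0] == pytest.approx(expected)

    def test_constant_input_flagged_as_nan(self):
        rho, p = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    @given(st.floats(0.2, 4.0))
    def test_invariant_under_monotone_transform_of_either(self, power):
        rng = np.random.default_rng(10)
        x = rng.random(30)
        y = x + rng.random(30)
        base = spearman_corr(x, y)[0]
        assert spearman_corr(x ** power, y)[0] == pytest.approx(base)
        assert spearman_corr(x, y ** power)[0] == pytest.approx(base)
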