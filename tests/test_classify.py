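"""Classification: logistic IRLS, AUC, LOSO CV, bootstrap, feature menu."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from specmdd.classify import (LosoResult, SELECTED_FEATURES, auc,
                              bootstrap_auc_ci, enumerate_feature_sets,
                              fit_logistic, loso_cv, run_menu)
from specmdd.features import design_columns


class TestFitLogistic:
    def test_symmetric_data_gives_zero_coefficients(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 1, 0, 1])
        fit = fit_logistic(X, y)
        assert fit.intercept == pytest.approx(0.0, abs=1e-8)
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(fit.predict_proba(X), 0.5)

    def test_separable_data_flags_separation_but_predicts(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        fit = fit_logistic(X, y, max_iter=60)
        assert fit.separation
        p = fit.predict_proba(X)
        assert p[0] < 0.5 < p[-1]

    def test_matches_direct_likelihood_maximization(self):
        """Coefficients agree with an independent derivative-free
        maximization of the log-likelihood on a small data set."""
        X = np.array([[0.2], [1.1], [-0.7], [0.5], [2.0], [-1.5], [0.9],
                      [-0.3]])
        y = np.array([1, 1, 0, 0, 1, 0, 1, 0])  # overlapping classes
        fit = fit_logistic(X, y)

        def nll(beta):
            eta = beta[0] + X[:, 0] * beta[1]
            return -np.sum(y * eta - np.logaddexp(0, eta))

        res = minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12})
        assert fit.intercept == pytest.approx(res.x[0], abs=1e-4)
        assert fit.coef[0] == pytest.approx(res.x[1], abs=1e-4)

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 3))
        eta = 0.3 + X @ np.array([0.8, -0.5, 0.0])
        y = (rng.random(60) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0).params
        assert fit.intercept == pytest.approx(ref[0], abs=1e-6)
        np.testing.assert_allclose(fit.coef, ref[1:], atol=1e-6)

    def test_rejects_constant_labels(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones((4, 1)), np.ones(4))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_pair_enumeration_example(self):
        # 3 of 4 (positive, negative) pairs concordant
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_ties_count_half(self):
        assert auc([0.5, 0.5], [0, 1]) == 0.5

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        s = rng.random(50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        assert auc(np.exp(4 * s), y) == pytest.approx(auc(s, y))

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(4)
        s = rng.random(10_000)
        y = rng.integers(0, 2, 10_000)
        assert auc(s, y) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


def _feature_table(rng, n_hc=74, n_mdd=40, effect=0.0):
    """Feature-level table with a standardized gap on the three selected
    dual-component columns."""
    n = n_hc + n_mdd
    cols = design_columns()
    data = {c: rng.standard_normal(n) for c in cols}
    for key in ("electrode_periodic_parietal_theta",
                "electrode_periodic_frontal_alpha",
                "electrode_aperiodic_parietal"):
        data[key][n_hc:] -= effect
    data["group"] = ["HC"] * n_hc + ["MDD"] * n_mdd
    df = pd.DataFrame(data)
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    return df


class TestLoso:
    def test_one_fold_per_subject(self):
        rng = np.random.default_rng(5)
        table = _feature_table(rng, 20, 15, effect=1.0)
        res = loso_cv(table, ["electrode_periodic_parietal_theta"])
        assert len(res.probabilities) == 35
        assert len(set(res.subject_ids)) == 35

    def test_invariant_to_subject_ordering(self):
        rng = np.random.default_rng(6)
        table = _feature_table(rng, 15, 12, effect=0.8)
        res = loso_cv(table, ["electrode_periodic_parietal_theta"])
        shuffled = table.sample(frac=1.0, random_state=1)
        res2 = loso_cv(shuffled, ["electrode_periodic_parietal_theta"])
        a = dict(zip(res.subject_ids, res.probabilities))
        b = dict(zip(res2.subject_ids, res2.probabilities))
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-10)
        assert res.auc == pytest.approx(res2.auc, abs=1e-10)

    def test_unknown_key_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(KeyError):
            loso_cv(_feature_table(rng, 10, 10), ["no_such_feature"])

    def test_uninformative_noise_feature_stays_near_chance(self):
        rng = np.random.default_rng(8)
        aucs = [loso_cv(_feature_table(rng), ["source_psd_frontal_theta"]).auc
                for _ in range(5)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)


class TestBootstrap:
    def _result(self, rng, mu=1.0, n_pos=40, n_neg=74):
        s = np.concatenate([rng.normal(mu, 1, n_pos), rng.normal(0, 1, n_neg)])
        y = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
        return LosoResult("t", [str(i) for i in range(len(y))], y, s,
                          auc(s, y))

    def test_fixed_seed_reproducible(self):
        res = self._result(np.random.default_rng(9))
        assert bootstrap_auc_ci(res, 500, seed=3) == \
            bootstrap_auc_ci(res, 500, seed=3)

    def test_perfect_separation_degenerate_ci(self):
        y = np.array([0] * 10 + [1] * 10)
        s = y.astype(float)
        res = LosoResult("t", [str(i) for i in range(20)], y, s, 1.0)
        assert bootstrap_auc_ci(res, 200, seed=0) == (1.0, 1.0)

    def test_nominal_coverage(self):
        """Percentile-bootstrap 95% CI covers the population AUC at close to
        nominal rate over simulated score sets."""
        pop_auc = norm.cdf(1.0 / np.sqrt(2))
        cover = 0
        reps = 200
        for i in range(reps):
            res = self._result(np.random.default_rng(100 + i))
            lo, hi = bootstrap_auc_ci(res, 300, seed=i)
            cover += lo <= pop_auc <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.035)


class TestMenu:
    def test_menu_has_ten_sets_with_expected_kinds(self):
        sets = enumerate_feature_sets()
        assert len(sets) == 10
        kinds = [s.kind for s in sets]
        assert kinds.count("single") == 5
        assert kinds.count("by_band") == 2
        assert kinds.count("by_analysis_type") == 2
        assert kinds.count("dual_component") == 1

    def test_dual_component_set_has_three_features(self):
        dual = [s for s in enumerate_feature_sets()
                if s.kind == "dual_component"][0]
        assert len(dual.keys) == 3
        assert "electrode_aperiodic_parietal" in dual.keys

    def test_all_keys_exist_in_designed_table(self):
        cols = set(design_columns())
        for s in enumerate_feature_sets():
            assert set(s.keys) <= cols

    def test_unknown_selected_feature_rejected(self):
        with pytest.raises(KeyError):
            enumerate_feature_sets({"bogus": "electrode_psd_frontal_alpha"})

    def test_run_menu_is_deterministic(self):
        rng = np.random.default_rng(11)
        table = _feature_table(rng, 30, 20, effect=0.8)
        a = run_menu(table, n_boot=100, seed=5)
        b = run_menu(table, n_boot=100, seed=5)
        for ra, rb in zip(a, b):
            assert (ra.auc, ra.ci_low, ra.ci_high) == \
                (rb.auc, rb.ci_low, rb.ci_high)
        assert SELECTED_FEATURES["parietal_aperiodic"] == \
            "electrode_aperiodic_parietal"
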