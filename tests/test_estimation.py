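"""IRLS core, cluster sandwich, and the pooled MSM interfaces.

statsmodels serves as the independent oracle for the GLM coefficients and
the cluster-robust covariance; the package's own fitter never calls it.
"""

import numpy as np
import pytest
import statsmodels.api as sm

from stuntmsm import (MarginalStructuralModel, RankDeficientError,
                      SeparationError, cluster_robust_cov,
                      fit_weighted_logistic)
from stuntmsm.estimation import WeightedLogit

from conftest import random_logit_data


def _two_by_two():
    """Exposed: 10 events / 20 non-events; unexposed: 30 / 40."""
    y = np.concatenate([np.ones(10), np.zeros(20), np.ones(30), np.zeros(40)])
    a = np.concatenate([np.ones(30), np.zeros(70)])
    X = np.column_stack([np.ones(100), a])
    return X, y


class TestWeightedLogit:
    def test_two_by_two_equals_cross_product_ratio(self):
        X, y = _two_by_two()
        res = fit_weighted_logistic(X, y)
        assert np.exp(res.params[1]) == pytest.approx(10 * 40 / (20 * 30),
                                                      abs=1e-8)

    def test_weight_scale_invariance(self, rng):
        X, y, w, _ = random_logit_data(rng)
        a = fit_weighted_logistic(X, y, weights=w).params
        b = fit_weighted_logistic(X, y, weights=37.5 * w).params
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_matches_reference_glm(self, rng):
        for _ in range(20):
            X, y, w, _ = random_logit_data(rng)
            ours = fit_weighted_logistic(X, y, weights=w)
            ref = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=w).fit()
            np.testing.assert_allclose(ours.params, ref.params, atol=1e-8)
            np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-6)

    def test_fractional_outcome_self_consistency(self, rng):
        # refitting on the model's own fitted probabilities returns the
        # same coefficients: the score is exactly zero there
        X, y, w, _ = random_logit_data(rng)
        first = fit_weighted_logistic(X, y, weights=w)
        refit = fit_weighted_logistic(X, first.fittedvalues, weights=w)
        np.testing.assert_allclose(refit.params, first.params, atol=1e-6)

    def test_constant_outcome_is_separation(self):
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        with pytest.raises(SeparationError):
            fit_weighted_logistic(X, np.ones(30))

    def test_perfect_separation_detected(self):
        x = np.concatenate([-np.ones(20), np.ones(20)])
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones(40), x])
        with pytest.raises(SeparationError):
            fit_weighted_logistic(X, y)

    def test_rank_deficiency_names_columns(self, rng):
        X, y, _, _ = random_logit_data(rng)
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(RankDeficientError, match="x"):
            WeightedLogit(y, X2)

    def test_hard_fit_with_large_coefficients_converges(self, rng):
        # strong effects require the step-halved IRLS; plain Newton from
        # the null start diverges on data like this
        n = 2000
        x = rng.normal(size=n)
        lp = -4.0 + 5.0 * (x > 0.5)
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        X = np.column_stack([np.ones(n), (x > 0.5).astype(float), x])
        ours = fit_weighted_logistic(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)


class TestClusterRobust:
    def test_matches_reference_sandwich(self, rng):
        for _ in range(20):
            X, y, w, g = random_logit_data(rng)
            ours = fit_weighted_logistic(X, y, weights=w)
            cov = cluster_robust_cov(ours, g)
            ref = sm.GLM(y, X, family=sm.families.Binomial(),
                         freq_weights=w).fit(
                cov_type="cluster",
                cov_kwds={"groups": g, "use_correction": False})
            np.testing.assert_allclose(cov, ref.cov_params(), atol=1e-8)

    def test_singleton_clusters_equal_hc0(self, rng):
        X, y, _, _ = random_logit_data(rng)
        ours = fit_weighted_logistic(X, y)
        cov = cluster_robust_cov(ours, np.arange(len(y)))
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        np.testing.assert_allclose(cov, ref.cov_params(), atol=1e-9)

    def test_duplication_with_halved_weights_invariant(self):
        # duplicating each row within its cluster at half weight changes
        # neither the coefficients nor the clustered covariance
        X = np.column_stack([np.ones(6), [0, 0, 1, 1, 2, 2.0],
                             [1, 0, 1, 0, 1, 0.0]])
        y = np.array([1, 0, 1, 1, 0, 1.0])
        g = np.array([0, 0, 1, 1, 2, 2])
        base = fit_weighted_logistic(X, y)
        cov = cluster_robust_cov(base, g)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        g2 = np.concatenate([g, g])
        half = fit_weighted_logistic(X2, y2, weights=np.full(12, 0.5))
        cov2 = cluster_robust_cov(half, g2)
        np.testing.assert_allclose(base.params, half.params, atol=1e-8)
        np.testing.assert_allclose(cov, cov2, atol=1e-8)

    def test_cr1_is_scaled_cr0(self, rng):
        X, y, w, g = random_logit_data(rng)
        fit = fit_weighted_logistic(X, y, weights=w)
        cr0 = cluster_robust_cov(fit, g)
        cr1 = cluster_robust_cov(fit, g, correction="cr1")
        gsize = len(np.unique(g))
        np.testing.assert_allclose(cr1, cr0 * gsize / (gsize - 1), atol=1e-12)

    def test_robust_close_to_model_se_under_independence(self, rng):
        X, y, _, _ = random_logit_data(rng, n=4000, clusters=4000)
        fit = fit_weighted_logistic(X, y)
        robust = np.sqrt(np.diag(cluster_robust_cov(fit, np.arange(4000))))
        assert np.all(np.abs(robust / fit.bse - 1.0) < 0.2)

    def test_too_few_clusters_rejected(self, rng):
        X, y, _, _ = random_logit_data(rng, n=50)
        fit = fit_weighted_logistic(X, y)
        with pytest.raises(ValueError):
            cluster_robust_cov(fit, np.zeros(50))


class TestMSMInterfaces:
    def test_permutation_invariance(self, analysis_table):
        from stuntmsm.pipeline import fit_scenario
        res = fit_scenario(analysis_table, "all_waves")
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(analysis_table))
        shuffled = analysis_table.iloc[perm].reset_index(drop=True)
        res2 = fit_scenario(shuffled, "all_waves")
        assert res["msm"].log_or == pytest.approx(res2["msm"].log_or,
                                                  abs=1e-10)
        assert res["msm"].log_or_se == pytest.approx(res2["msm"].log_or_se,
                                                     abs=1e-10)

    def test_unit_weights_single_wave_equals_plain_logit(self, analysis_table):
        one_wave = analysis_table[analysis_table["wave"] == 1].copy()
        m = MarginalStructuralModel(one_wave, weights=np.ones(len(one_wave)),
                                    scenario="all_waves")
        plain = MarginalStructuralModel(one_wave, scenario="all_waves")
        assert m.fit().log_or == pytest.approx(plain.fit().log_or, abs=1e-10)

    def test_missing_values_rejected(self, analysis_table):
        broken = analysis_table.copy()
        broken.loc[broken.index[3], "stunted"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            MarginalStructuralModel(broken)

    def test_cumulative_exposure_parameterization(self, analysis_table):
        # per-wave dose coefficient: weaker per unit than the current-
        # status contrast, same direction
        cur = MarginalStructuralModel(analysis_table).fit()
        dose = MarginalStructuralModel(analysis_table,
                                       exposure="cumulative").fit()
        assert dose.log_or < 0
        assert abs(dose.log_or) < abs(cur.log_or)

    def test_result_invariants(self, analysis_table):
        res = MarginalStructuralModel(analysis_table).fit()
        assert res.ci_low <= res.or_estimate <= res.ci_high
        assert 0 <= res.p_value <= 1
        assert res.or_estimate == pytest.approx(np.exp(res.log_or))
        assert "pooled logistic" in res.summary()
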