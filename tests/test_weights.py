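"""Stabilized IPT weights: construction, diagnostics, positivity, balance."""


import numpy as np
import pandas as pd
import pytest

from stuntmsm import (PositivityError, SeparationError, WeightModelSpec,
                      build_analysis_table, compute_stabilized_weights,
                      covariate_balance, default_config, fit_exposure_models,
                      generate_cohort, positivity_check, weight_diagnostics)
from stuntmsm.weights import WeightSet
from stuntmsm.simulate import StuntingProcess


class _FakeFit:
    """Duck-typed exposure model returning fixed stunting probabilities."""

    def __init__(self, p):
        self.p = np.asarray(p, dtype=float)

    def predict(self, table):
        return self.p


def _tiny_table():
    return pd.DataFrame({
        "child_id": [0, 0], "wave": [1, 2], "stunted": [1.0, 1.0],
    })


class TestComputeWeights:
    def test_printed_two_wave_example(self):
        # observed-exposure probabilities: numerator (0.3, 0.4),
        # denominator (0.5, 0.8) -> cumulative 0.6 then 0.3
        tab = _tiny_table()
        wset = compute_stabilized_weights(
            (_FakeFit([0.3, 0.4]), _FakeFit([0.5, 0.8])), tab)
        np.testing.assert_allclose(wset.sw_t, [0.6, 0.5])
        np.testing.assert_allclose(wset.sw_cum, [0.6, 0.3])

    def test_unexposed_probabilities_complemented(self):
        tab = _tiny_table()
        tab["stunted"] = [0.0, 0.0]
        wset = compute_stabilized_weights(
            (_FakeFit([0.3, 0.4]), _FakeFit([0.5, 0.8])), tab)
        np.testing.assert_allclose(wset.sw_t, [0.7 / 0.5, 0.6 / 0.2])

    def test_identical_models_give_unit_weights(self, analysis_table):
        spec = WeightModelSpec(
            numerator_covariates=WeightModelSpec().denominator_covariates)
        fits = fit_exposure_models(analysis_table, spec)
        wset = compute_stabilized_weights(fits, analysis_table)
        np.testing.assert_allclose(wset.sw_cum, 1.0, atol=1e-10)

    def test_degenerate_probability_is_positivity_error(self):
        tab = _tiny_table()
        with pytest.raises(PositivityError):
            compute_stabilized_weights(
                (_FakeFit([0.3, 0.4]), _FakeFit([1.0, 0.8])), tab)

    def test_mean_close_to_one_on_default_cohort(self, analysis_table):
        fits = fit_exposure_models(analysis_table)
        wset = compute_stabilized_weights(fits, analysis_table)
        assert abs(wset.sw_cum.mean() - 1.0) < 0.05

    def test_invariant_to_child_order(self, analysis_table):
        fits = fit_exposure_models(analysis_table)
        base = compute_stabilized_weights(fits, analysis_table)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(analysis_table))
        shuffled = analysis_table.iloc[perm].reset_index(drop=True)
        fits2 = fit_exposure_models(shuffled)
        wset2 = compute_stabilized_weights(fits2, shuffled)
        a = base.frame.set_index(["child_id", "wave"])["sw_cum"]
        b = wset2.frame.set_index(["child_id", "wave"])["sw_cum"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index(),
                                       atol=1e-10, rtol=0)

    def test_constant_exposure_is_separation_error(self, analysis_table):
        broken = analysis_table.copy()
        broken["stunted"] = 1.0
        with pytest.raises(SeparationError, match="exposure model"):
            fit_exposure_models(broken)

    def test_missing_values_rejected(self, analysis_table):
        broken = analysis_table.copy()
        broken.loc[broken.index[0], "log_pc_income"] = np.nan
        with pytest.raises(ValueError, match="log_pc_income"):
            fit_exposure_models(broken)

    def test_per_wave_pooling_runs(self, analysis_table):
        spec = WeightModelSpec(pooling="per_wave")
        fits = fit_exposure_models(analysis_table, spec)
        wset = compute_stabilized_weights(fits, analysis_table)
        assert abs(wset.sw_cum.mean() - 1.0) < 0.05


class TestWeightModelSpec:
    def test_numerator_must_nest_in_denominator(self):
        with pytest.raises(ValueError, match="not in denominator"):
            WeightModelSpec(numerator_covariates=("stunted_lag", "shoe_size"))

    def test_lagged_exposure_required(self):
        with pytest.raises(ValueError, match="stunted_lag"):
            WeightModelSpec(numerator_covariates=("male",),
                            denominator_covariates=("male", "stunted_lag"))

    def test_exposure_unrelated_to_covariates_has_null_coefficients(self):
        # when the generator gives stunting no covariate loadings, the
        # fitted denominator coefficients on L should be indistinguishable
        # from zero
        cfg = default_config().replace(n_children=4000, seed=31)
        cfg = cfg.replace(haz_process=StuntingProcess(
            loading_log_pc_income=0.0, loading_any_illness=0.0,
            loading_household_size=0.0, loading_birthweight=0.0,
            loading_parental_edu=0.0, loading_male=0.0))
        table, _ = generate_cohort(cfg, compute_truth=False)
        analysis = build_analysis_table(table)
        _, den = fit_exposure_models(analysis)
        _, fit = den.fits[None]
        for col in ("log_pc_income", "any_illness", "birthweight_kg"):
            j = fit.model.exog_names.index(col)
            assert abs(fit.params[j]) < 3 * fit.bse[j]


class TestDiagnostics:
    def test_unit_weights_summary(self):
        frame = pd.DataFrame({"child_id": range(5), "wave": 1,
                              "p_num": 0.5, "p_den": 0.5,
                              "sw_t": 1.0, "sw_cum": 1.0})
        d = weight_diagnostics(WeightSet(frame))
        assert d["mean"] == 1.0 and d["sd"] == 0.0
        assert d["min"] == d["max"] == 1.0

    def test_truncation_clamps_to_percentiles(self, analysis_table):
        fits = fit_exposure_models(analysis_table)
        wset = compute_stabilized_weights(fits, analysis_table)
        d = weight_diagnostics(wset, truncation_percentiles=(1, 99))
        lo, hi = d["truncation_bounds"]
        trunc = d["truncated"]
        assert trunc.sw_cum.min() == pytest.approx(lo)
        assert trunc.sw_cum.max() == pytest.approx(hi)
        assert d["n_outside_truncation"] > 0

    def test_empty_weight_set_rejected(self):
        empty = WeightSet(pd.DataFrame(
            columns=["child_id", "wave", "p_num", "p_den", "sw_t", "sw_cum"]))
        with pytest.raises(ValueError):
            weight_diagnostics(empty)


class TestPositivity:
    def test_default_cohort_gender_by_urban_is_positive(self, analysis_table):
        rep = positivity_check(analysis_table, ["male", "urban"])
        assert len(rep) == 4
        assert not rep["flagged"].any()

    def test_empty_cell_flagged(self, analysis_table):
        broken = analysis_table.copy()
        broken.loc[broken["male"] == 1.0, "stunted"] = 0.0
        rep = positivity_check(broken, ["male"])
        assert rep.loc[rep["male"] == 1.0, "flagged"].all()

    def test_continuous_column_rejected(self, analysis_table):
        with pytest.raises(ValueError, match="continuous"):
            positivity_check(analysis_table, ["log_pc_income"])


class TestBalance:
    def test_weighting_shrinks_covariate_imbalance(self, analysis_table):
        fits = fit_exposure_models(analysis_table)
        wset = compute_stabilized_weights(fits, analysis_table)
        raw = covariate_balance(analysis_table)
        weighted = covariate_balance(analysis_table, wset)
        assert weighted["smd"].abs().mean() < raw["smd"].abs().mean()


def test_weight_histogram_written(analysis_table, tmp_path):
    from stuntmsm.weights import plot_weight_histogram
    fits = fit_exposure_models(analysis_table)
    wset = compute_stabilized_weights(fits, analysis_table)
    out = tmp_path / "weights.png"
    plot_weight_histogram(wset, path=out)
    assert out.exists() and out.stat().st_size > 0
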