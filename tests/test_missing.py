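"""Chained-equation imputation, Rubin pooling, complete-case filtering."""


import numpy as np
import pandas as pd
import pytest

from stuntmsm import (apply_missingness, build_analysis_table,
                      complete_case_filter, default_config, generate_cohort,
                      mice_impute, pool_rubin)
from stuntmsm.pipeline import fit_scenario, fit_scenario_multiply_imputed
from stuntmsm.simulate import TIME_VARYING_COLUMNS


@pytest.fixture(scope="module")
def incomplete_cohort():
    cfg = default_config().replace(seed=41)
    table, _ = generate_cohort(cfg, compute_truth=False)
    return cfg, table, apply_missingness(table, cfg, seed=42)


class TestMiceImpute:
    def test_complete_input_returns_identical_copies(self):
        cfg = default_config().replace(n_children=250, seed=43)
        table, _ = generate_cohort(cfg, compute_truth=False)
        stack = mice_impute(table, m=3, cycles=2, seed=44)
        assert stack.m == 3
        for comp in stack.completed_tables:
            pd.testing.assert_frame_equal(comp, table)

    def test_completed_tables_have_no_missing_analysis_values(
            self, incomplete_cohort):
        _, _, miss = incomplete_cohort
        stack = mice_impute(miss, m=2, cycles=3, seed=45)
        cols = ["haz", "stunted"] + TIME_VARYING_COLUMNS
        for comp in stack.completed_tables:
            expo = comp[comp["wave"] <= 4]
            assert expo[cols].notna().all().all()
            last = comp[comp["wave"] == 5]
            assert last["grade_outcome"].notna().all()
            assert last["highest_grade_completed"].notna().all()

    def test_binary_columns_imputed_in_zero_one(self, incomplete_cohort):
        _, _, miss = incomplete_cohort
        stack = mice_impute(miss, m=2, cycles=3, seed=46)
        for comp in stack.completed_tables:
            expo = comp[comp["wave"] <= 4]
            for col in ("stunted", "any_illness", "urban", "grant_receipt",
                        "lives_with_both_parents"):
                assert set(np.unique(expo[col])) <= {0.0, 1.0}
            assert set(np.unique(
                comp.loc[comp["wave"] == 5, "grade_outcome"])) <= {0.0, 1.0}

    def test_haz_consistent_with_imputed_indicator(self, incomplete_cohort):
        _, _, miss = incomplete_cohort
        comp = mice_impute(miss, m=1, cycles=3, seed=47).completed_tables[0]
        expo = comp[comp["wave"] <= 4]
        assert (((expo["haz"] < -2.0) == (expo["stunted"] == 1.0))).all()

    def test_observed_values_never_overwritten(self, incomplete_cohort):
        _, _, miss = incomplete_cohort
        comp = mice_impute(miss, m=1, cycles=2, seed=48).completed_tables[0]
        for col in ("stunted", "log_pc_income"):
            obs = miss[col].notna()
            pd.testing.assert_series_equal(comp.loc[obs, col],
                                           miss.loc[obs, col])

    def test_pmm_draws_come_from_observed_support(self, incomplete_cohort):
        _, _, miss = incomplete_cohort
        comp = mice_impute(miss, m=1, cycles=2, seed=57,
                           method="pmm").completed_tables[0]
        expo_miss = miss["wave"] <= 4
        was = miss.loc[expo_miss, "log_pc_income"].isna()
        observed = set(miss.loc[expo_miss, "log_pc_income"].dropna())
        imputed = comp.loc[expo_miss, "log_pc_income"][was.to_numpy()]
        assert imputed.notna().all()
        assert set(imputed) <= observed

    def test_fully_missing_column_rejected(self, incomplete_cohort):
        _, _, miss = incomplete_cohort
        broken = miss.copy()
        broken.loc[broken["wave"] <= 4, "log_pc_income"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            mice_impute(broken, m=2, cycles=2, seed=49)

    def test_mcar_income_pooled_estimate_tracks_complete_data(self):
        # 20% MCAR on log-income only: the pooled weighted estimate should
        # sit within Monte-Carlo range of the complete-data estimate
        cfg = default_config().replace(seed=50)
        table, _ = generate_cohort(cfg, compute_truth=False)
        full = fit_scenario(build_analysis_table(table), "all_waves")["msm"]
        rng = np.random.default_rng(51)
        miss = table.copy()
        expo = miss["wave"] <= 4
        knock = expo & (rng.random(len(miss)) < 0.2)
        miss.loc[knock, "log_pc_income"] = np.nan
        pooled = fit_scenario_multiply_imputed(miss, "all_waves", m=5,
                                               cycles=5, seed=52)["msm"]
        assert abs(pooled.point - full.log_or) < 3 * full.log_or_se


class TestPoolRubin:
    def test_hand_arithmetic_example(self):
        # estimates {0, 2}, variances {1, 1}, m=2:
        # mean 1, B = 2, T = 1 + 1.5 * 2 = 4
        p = pool_rubin([0.0, 2.0], [1.0, 1.0])
        assert p.point == 1.0
        assert p.within_var == 1.0
        assert p.between_var == 2.0
        assert p.total_var == 4.0

    @pytest.mark.parametrize("m", [2, 3, 5])
    def test_formulas_match_hand_computation(self, m, rng):
        q = rng.normal(size=m)
        u = rng.uniform(0.5, 1.5, m)
        p = pool_rubin(q, u)
        assert p.point == pytest.approx(q.mean())
        assert p.within_var == pytest.approx(u.mean())
        assert p.between_var == pytest.approx(q.var(ddof=1))
        assert p.total_var == pytest.approx(u.mean()
                                            + (1 + 1 / m) * q.var(ddof=1))
        assert p.ci_low <= p.or_estimate <= p.ci_high

    def test_identical_estimates_have_zero_between_variance(self):
        p = pool_rubin([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        assert p.between_var == 0.0
        assert p.total_var == p.within_var

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([0.5], [0.2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([0.5, 0.6], [0.2])

    def test_barnard_rubin_df_below_complete_data_df(self):
        p = pool_rubin([0.4, 0.6, 0.5], [0.04, 0.05, 0.045], df_com=1000)
        assert p.df < 1000


class TestCompleteCase:
    def test_no_missingness_is_identity(self):
        cfg = default_config().replace(n_children=200, seed=53)
        table, _ = generate_cohort(cfg, compute_truth=False)
        kept, report = complete_case_filter(table)
        assert report["n_children_dropped"] == 0
        pd.testing.assert_frame_equal(kept, table)

    def test_wave3_gap_drops_child_only_under_all_waves(self):
        cfg = default_config().replace(n_children=150, seed=54)
        table, _ = generate_cohort(cfg, compute_truth=False)
        table.loc[(table["child_id"] == 7) & (table["wave"] == 3),
                  "haz"] = np.nan
        table.loc[(table["child_id"] == 7) & (table["wave"] == 3),
                  "stunted"] = np.nan
        kept_all, _ = complete_case_filter(table, "all_waves")
        assert 7 not in kept_all["child_id"].unique()
        kept_early, _ = complete_case_filter(table, "early_only")
        assert 7 in kept_early["child_id"].unique()

    def test_missing_outcome_drops_child(self):
        cfg = default_config().replace(n_children=150, seed=55)
        table, _ = generate_cohort(cfg, compute_truth=False)
        table.loc[(table["child_id"] == 3) & (table["wave"] == 5),
                  "grade_outcome"] = np.nan
        kept, _ = complete_case_filter(table, "early_only")
        assert 3 not in kept["child_id"].unique()

    def test_everything_missing_rejected(self):
        cfg = default_config().replace(n_children=20, seed=56)
        table, _ = generate_cohort(cfg, compute_truth=False)
        table.loc[table["wave"] == 2, "stunted"] = np.nan
        with pytest.raises(ValueError, match="no complete cases"):
            complete_case_filter(table, "all_waves")
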