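"""Estimators: naive methods, EM, MI data augmentation, Rubin pooling, combinations."""

import math

import numpy as np
import pandas as pd
import pytest

from costmiss import (
    DropoutPatternConfig,
    MIConfig,
    combination_impute,
    complete_case_estimate,
    dropout_pattern_mask,
    em_mvn,
    fixed_cost_impute,
    grouped_means_impute,
    mcar_mask,
    mi_mcmc,
    mi_mean_estimate,
    mnar_mask,
    pool_rubin,
)
from costmiss.imputation import EstimationError

FAST_MI = MIConfig(m=5, burn_in=150, thin=30, seed=0)


def make_mask(cohort, missing_ids, reason="generic"):
    return pd.DataFrame({
        "patient_id": cohort["patient_id"],
        "is_missing": cohort["patient_id"].isin(missing_ids),
        "reason": np.where(cohort["patient_id"].isin(missing_ids), reason, "observed"),
    })


class TestCompleteCase:
    def test_arithmetic(self, tiny_cohort):
        sub = tiny_cohort.head(3).copy()
        sub["cost_total"] = [100.0, 200.0, 300.0]
        mean, se = complete_case_estimate(sub, make_mask(sub, {"T2"}))
        assert mean == pytest.approx(150.0)
        assert se == pytest.approx(np.std([100, 200], ddof=1) / np.sqrt(2))

    def test_no_missing_equals_full_mean(self, tiny_cohort):
        mean, _ = complete_case_estimate(tiny_cohort, None)
        assert mean == pytest.approx(tiny_cohort["cost_total"].mean())

    def test_too_few_observed(self, tiny_cohort):
        with pytest.raises(EstimationError):
            complete_case_estimate(tiny_cohort,
                                   make_mask(tiny_cohort, set(tiny_cohort["patient_id"][:5])))


class TestGroupedMeans:
    def test_group_mean_fill(self):
        df = pd.DataFrame({
            "patient_id": ["a", "b", "c"],
            "mmse": [24, 25, 23],                       # all mild
            "cost_total": [1000.0, 2000.0, 5000.0],
        })
        out = grouped_means_impute(df, make_mask(df, {"c"}))
        assert out.loc[2, "cost_total"] == pytest.approx(1500.0)

    def test_identity_without_missing(self, tiny_cohort):
        out = grouped_means_impute(tiny_cohort, None)
        pd.testing.assert_series_equal(out["cost_total"], tiny_cohort["cost_total"])

    def test_each_group_mean_equals_observed_mean(self, cohort_analysis):
        from costmiss import severity_group

        mask = mcar_mask(cohort_analysis, 0.3, seed=8)
        out = grouped_means_impute(cohort_analysis, mask)
        groups = severity_group(cohort_analysis["mmse"].to_numpy())
        miss = mask["is_missing"].to_numpy()
        for g in np.unique(groups):
            obs_mean = cohort_analysis.loc[(groups == g) & ~miss, "cost_total"].mean()
            assert out.loc[groups == g, "cost_total"].mean() == pytest.approx(obs_mean)

    def test_empty_group_falls_back_to_overall(self, caplog):
        import logging

        df = pd.DataFrame({
            "patient_id": ["a", "b", "c"],
            "mmse": [25, 24, 10],                       # severe group fully missing
            "cost_total": [1000.0, 3000.0, 9000.0],
        })
        with caplog.at_level(logging.WARNING):
            out = grouped_means_impute(df, make_mask(df, {"c"}))
        assert out.loc[2, "cost_total"] == pytest.approx(2000.0)
        assert any("fall" in r.message for r in caplog.records)


class TestFixedCost:
    def test_reason_filter_semantics(self, tiny_cohort):
        mask = make_mask(tiny_cohort, {"T0"}, reason="institutionalised")
        mask.loc[mask["patient_id"] == "T1", ["is_missing", "reason"]] = [True, "died"]
        out = fixed_cost_impute(tiny_cohort, mask, 2940.0)
        assert out.loc[0, "cost_total"] == 2940.0
        assert out.loc[1, "cost_total"] == pytest.approx(tiny_cohort.loc[1, "cost_total"])

    def test_zero_fixed_cost(self, tiny_cohort):
        mask = make_mask(tiny_cohort, {"T0"}, reason="institutionalised")
        out = fixed_cost_impute(tiny_cohort, mask, 0.0)
        assert out.loc[0, "cost_total"] == 0.0


class TestEmMvn:
    def test_complete_data_fixed_point(self, rng):
        x = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.6], [0.6, 1.0]], 400)
        p = em_mvn(pd.DataFrame(x, columns=["u", "v"]))
        assert np.allclose(p.mean, x.mean(axis=0), atol=1e-6)
        ml_cov = np.cov(x.T, ddof=0)
        assert np.allclose(p.cov, ml_cov, atol=1e-4)

    def test_univariate_observed_mle(self):
        p = em_mvn(pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan]}))
        assert p.mean[0] == pytest.approx(2.0)

    def test_parameter_recovery_under_mcar(self, rng):
        mean, cov = np.array([5.0, 10.0]), np.array([[4.0, 2.4], [2.4, 9.0]])
        x = rng.multivariate_normal(mean, cov, 2000)
        df = pd.DataFrame(x, columns=["a", "b"])
        df.loc[rng.random(2000) < 0.2, "a"] = np.nan
        p = em_mvn(df)
        assert np.allclose(p.mean, mean, atol=0.2)
        assert np.allclose(p.cov, cov, atol=0.6)

    def test_loglik_improves_over_start(self, rng):
        from costmiss.imputation import _observed_loglik, _pattern_groups

        x = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], 300)
        df = pd.DataFrame(x, columns=["a", "b"])
        df.loc[rng.random(300) < 0.3, "b"] = np.nan
        y = df.to_numpy()
        miss = np.isnan(y)
        pats = _pattern_groups(miss)
        start_ll = _observed_loglik(
            y, miss, np.nanmean(y, axis=0),
            np.diag(np.nanvar(y, axis=0)), pats,
        )
        p = em_mvn(df)
        assert p.loglik > start_ll

    def test_all_missing_variable_rejected(self):
        with pytest.raises(EstimationError):
            em_mvn(pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]}))


class TestMiMcmc:
    def test_no_missing_returns_identical_copies(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        out = mi_mcmc(df, MIConfig(m=3, burn_in=5, thin=2, seed=1))
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c, df)

    def test_observed_cells_preserved_across_imputations(self, rng):
        x = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 200)
        df = pd.DataFrame(x, columns=["a", "b"])
        miss = rng.random(200) < 0.25
        df.loc[miss, "a"] = np.nan
        out = mi_mcmc(df, FAST_MI)
        for c in out:
            assert np.allclose(c.loc[~miss, "a"], x[~miss, 0])
            assert np.allclose(c["b"], x[:, 1])
            assert c["a"].notna().all()

    def test_imputations_differ_between_draws(self, rng):
        x = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 200)
        df = pd.DataFrame(x, columns=["a", "b"])
        miss = rng.random(200) < 0.25
        df.loc[miss, "a"] = np.nan
        out = mi_mcmc(df, FAST_MI)
        assert not np.allclose(out[0].loc[miss, "a"], out[1].loc[miss, "a"])

    def test_parallel_chains_topology(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        df.loc[rng.random(80) < 0.2, "a"] = np.nan
        cfg = MIConfig(m=3, burn_in=50, thin=10, chains="parallel", seed=2)
        out = mi_mcmc(df, cfg)
        assert len(out) == 3
        assert all(c["a"].notna().all() for c in out)

    def test_floor_at_zero_clips_only_imputed(self, rng):
        df = pd.DataFrame({"a": [-5.0, 1.0, np.nan, np.nan, 2.0] * 20,
                           "b": rng.normal(size=100)})
        cfg = MIConfig(m=2, burn_in=20, thin=5, floor_at_zero=True, seed=3)
        out = mi_mcmc(df, cfg)
        for c in out:
            assert (c.loc[df["a"].isna(), "a"] >= 0).all()
            assert c.loc[0, "a"] == -5.0  # observed negative left alone

    @pytest.mark.parametrize("bad", [
        {"m": 1}, {"thin": 0}, {"burn_in": -1}, {"prior": "flat"}, {"chains": "three"},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            MIConfig(**bad).validate()


class TestPoolRubin:
    def test_degenerate_between_variance(self):
        p = pool_rubin([2000.0] * 3, [50.0] * 3)
        assert p.estimate == 2000.0
        assert p.standard_error == pytest.approx(50.0)
        assert math.isinf(p.df)

    def test_hand_checked_between_only(self):
        # B = 20000, T = (1 + 1/2) * 20000 = 30000, SE = sqrt(30000)
        p = pool_rubin([1900.0, 2100.0], [0.0, 0.0])
        assert p.estimate == pytest.approx(2000.0)
        assert p.standard_error == pytest.approx(math.sqrt(30000.0))

    def test_total_variance_identity(self):
        p = pool_rubin([1900.0, 2000.0, 2150.0], [40.0, 55.0, 45.0])
        assert p.standard_error**2 == pytest.approx(
            p.within_variance + (1 + 1 / 3) * p.between_variance
        )

    def test_pooled_se_at_least_within_se(self):
        p = pool_rubin([1900.0, 2000.0, 2150.0], [40.0, 55.0, 45.0])
        assert p.standard_error >= math.sqrt(p.within_variance)

    def test_barnard_rubin_df_smaller_than_classic(self):
        classic = pool_rubin([1900.0, 2100.0], [50.0, 60.0])
        small = pool_rubin([1900.0, 2100.0], [50.0, 60.0], n_complete=30)
        assert small.df < classic.df

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            pool_rubin([2000.0], [50.0])


class TestObservedDataPreservation:
    """No imputation method may alter an observed cost."""

    @pytest.mark.parametrize("method", ["grouped_means", "fixed_cost"])
    def test_observed_untouched(self, cohort_analysis, method):
        # MI preservation is covered in TestMiMcmc.test_observed_cells_preserved...
        cohort = cohort_analysis.head(300).reset_index(drop=True)
        mask = mcar_mask(cohort, 0.2, seed=11)
        mask["reason"] = np.where(mask["is_missing"], "institutionalised", "observed")
        obs = ~mask["is_missing"].to_numpy()
        before = cohort["cost_total"].to_numpy()[obs]
        if method == "grouped_means":
            after = grouped_means_impute(cohort, mask)["cost_total"].to_numpy()[obs]
        else:
            after = fixed_cost_impute(cohort, mask, 2940.0)["cost_total"].to_numpy()[obs]
        assert np.array_equal(before, after)


class TestCombination:
    def test_scenario_b_reduces_to_fixed_cost(self, cohort_analysis):
        cohort = cohort_analysis.head(400).reset_index(drop=True)
        mask = mnar_mask(cohort, 0.1)
        mask["reason"] = np.where(mask["is_missing"], "institutionalised", "observed")
        p = combination_impute(cohort, mask, scenario="B", config=FAST_MI)
        expected = cohort["cost_total"].to_numpy().copy()
        expected[mask["is_missing"].to_numpy()] = 2940.0
        assert p.estimate == pytest.approx(expected.mean())

    def test_scenario_a_without_missing_is_full_mean(self, cohort_analysis):
        cohort = cohort_analysis.head(200).reset_index(drop=True)
        mask = dropout_pattern_mask(
            cohort, DropoutPatternConfig(rate_institutionalised=0.0, rate_died=0.0,
                                         rate_ltfu=0.0), seed=0)
        p = combination_impute(cohort, mask, scenario="A", config=FAST_MI)
        assert p.estimate == pytest.approx(cohort["cost_total"].mean())

    def test_generic_mask_rejected(self, cohort_analysis):
        cohort = cohort_analysis.head(100).reset_index(drop=True)
        with pytest.raises(ValueError, match="reason"):
            combination_impute(cohort, mcar_mask(cohort, 0.2, seed=1), scenario="A",
                               config=FAST_MI)
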