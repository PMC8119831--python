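import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
import wmnet
from wmnet.glm import (
    GlmFit,
    RankDeficientDesignError,
    batch_ols,
    cognition_models,
    disease_effect_model,
    fdr_correct,
    fit_glm,
    groupwise_contrast,
    select_model_by_aic,
)


def _fake_fit(aic, n=50, outcome="m"):
    z = np.zeros(3)
    return GlmFit(outcome, ["const", "a", "b"], z, z, z, z, n, n - 3, 1.0, aic)


class TestFitGlm:
    def test_noise_free_recovery(self):
        x = pd.DataFrame({"x": np.arange(10.0)})
        fit = fit_glm(2.0 * np.arange(10.0), x)
        beta, _, _ = fit.coef("x")
        assert beta == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n, k = 40, 4
            x = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            design = pd.DataFrame(x, columns=[f"v{i}" for i in range(k)])
            fit = fit_glm(y, design)
            xc = np.column_stack([np.ones(n), x])
            beta, se, t, p, rss = oracles.brute_ols(xc, y)
            assert np.allclose(fit.params, beta, atol=1e-8)
            assert np.allclose(fit.bse, se, atol=1e-8)
            assert np.allclose(fit.pvalues, p, atol=1e-8)
            assert fit.rss == pytest.approx(rss, rel=1e-10)
            assert fit.aic == pytest.approx(n * np.log(rss / n) + 2 * (k + 1), rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_batch_ols_agrees_with_fit_glm(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, k, q = 60, 5, 7
        x = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
        y = rng.normal(size=(n, q))
        res = batch_ols(x, y)
        for j in range(q):
            fit = fit_glm(
                y[:, j],
                pd.DataFrame(x, columns=["const"] + [f"v{i}" for i in range(k - 1)]),
            )
            assert np.allclose(res["beta"][:, j], fit.params, atol=1e-8)
            assert np.allclose(res["se"][:, j], fit.bse, atol=1e-8)
            assert np.allclose(res["p"][:, j], fit.pvalues, atol=1e-8)
            assert res["aic"][j] == pytest.approx(fit.aic, rel=1e-10)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficientDesignError, match="collinear columns.*'[ab]'"):
            fit_glm(rng.normal(size=30), design)

    def test_missing_rows_dropped(self):
        y = np.arange(20.0)
        x = pd.DataFrame({"x": np.arange(20.0)})
        y[3] = np.nan
        fit = fit_glm(y, x)
        assert fit.n == 19

    def test_type_one_error_calibrated(self):
        """y independent of x: rejection rate at alpha=.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(42)
        n, reps = 200, 1000
        rejections = 0
        for _ in range(reps):
            x = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.normal(size=n)
            res = batch_ols(x, y)
            rejections += res["p"][1, 0] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_planted_beta_recovered(self):
        """beta=0.5, noise SD 1, n=114: mean estimate within 3 MC SEs."""
        rng = np.random.default_rng(7)
        n, reps, true = 114, 500, 0.5
        est = np.empty(reps)
        for r in range(reps):
            x = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = true * x[:, 1] + rng.normal(size=n)
            est[r] = batch_ols(x, y)["beta"][1, 0]
        se_mc = est.std(ddof=1) / np.sqrt(reps)
        assert abs(est.mean() - true) < 3 * se_mc


class TestModelSelection:
    def test_nonsignificant_interaction_lower_aic_without(self):
        chosen, rat = select_model_by_aic(_fake_fit(120.0), _fake_fit(100.0), 0.60)
        assert rat["chosen"] == "without_interaction"

    def test_significant_interaction_kept_regardless_of_aic(self):
        chosen, rat = select_model_by_aic(_fake_fit(500.0), _fake_fit(100.0), 0.01)
        assert rat["chosen"] == "with_interaction"

    def test_aic_tie_prefers_simpler_model(self):
        chosen, rat = select_model_by_aic(_fake_fit(100.0), _fake_fit(100.0), 0.5)
        assert rat["chosen"] == "without_interaction"

    def test_mismatched_rows_rejected(self):
        with pytest.raises(ValueError, match="different rows"):
            select_model_by_aic(_fake_fit(1.0, n=50), _fake_fit(1.0, n=49), 0.5)

    def test_aic_prefers_generating_model_at_large_n(self):
        """On data generated without interaction, the superset model has
        higher AIC at large n."""
        rng = np.random.default_rng(9)
        n = 1000
        a = rng.integers(0, 2, n).astype(float)
        b = rng.integers(0, 2, n).astype(float)
        y = 1.0 + 0.5 * a - 0.7 * b + rng.normal(size=n)
        x0 = np.column_stack([np.ones(n), a, b])
        x1 = np.column_stack([x0, a * b])
        aic0 = batch_ols(x0, y)["aic"][0]
        aic1 = batch_ols(x1, y)["aic"][0]
        assert aic0 < aic1


class TestFdr:
    def test_single_p_identity(self):
        assert fdr_correct([0.01])[0] == pytest.approx(0.01)

    def test_stepup_hand_example(self):
        adj = fdr_correct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_hand_rolled_bh(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=92)
        assert np.allclose(fdr_correct(p), oracles.brute_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        p = np.asarray(pvals)
        adj = fdr_correct(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])


class TestCohortModels:
    def test_disease_model_predictor_roster(self, small_cohort):
        cohort, _ = small_cohort
        y = np.asarray(cohort["age"], float) * 0 + np.random.default_rng(0).normal(size=len(cohort))
        fit = disease_effect_model(y, cohort, with_interaction=True)
        assert fit.predictors == [
            "const", "adci", "lbci", "adci_x_lbci",
            "age", "sex", "education", "dwmh", "pwmh", "icv",
        ]

    def test_single_group_cohort_rejected(self, small_cohort):
        cohort, _ = small_cohort
        sub = cohort[cohort["group"] == "control"]
        with pytest.raises(ValueError, match="two groups"):
            disease_effect_model(np.zeros(len(sub)), sub)

    def test_contrast_with_itself_rejected(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="itself"):
            groupwise_contrast(np.zeros(len(cohort)), cohort, "control", "control")

    def test_contrast_empty_group_rejected(self, small_cohort):
        cohort, _ = small_cohort
        sub = cohort[cohort["group"].isin(["control", "mixed"])]
        with pytest.raises(ValueError, match="empty"):
            groupwise_contrast(np.zeros(len(sub)), sub, "control", "pure_lbci")

    def test_cognition_models_have_14_rows_each(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(5)
        out = cognition_models(cohort, rng.normal(size=len(cohort)), model2_disease="lbci")
        assert len(out["model1"].table) == 14
        assert len(out["model2"].table) == 14
        assert out["model1"].scope == "14 tests"

    def test_cognition_missing_scores_listed(self, small_cohort):
        cohort, _ = small_cohort
        broken = cohort.drop(columns=["k_mmse", "k_bnt"])
        with pytest.raises(ValueError, match="k_bnt"):
            cognition_models(broken, np.zeros(len(broken)))

    def test_model2_attenuates_disease_driven_association(self, small_cohort):
        """When cognition is driven by the disease flag, controlling for
        the flag shrinks the network-measure beta."""
        cohort, _ = small_cohort
        cohort = cohort.copy()
        rng = np.random.default_rng(21)
        n = len(cohort)
        # network measure depends on lbci; cognition depends only on lbci
        measure = -2.0 * cohort["lbci"] + rng.normal(size=n)
        for t in wmnet.COGNITION_TESTS:
            cohort[t] = -1.5 * cohort["lbci"] + 0.3 * rng.normal(size=n)
        out = cognition_models(cohort, measure, model2_disease="lbci")
        b1 = out["model1"].table["beta"].abs().mean()
        b2 = out["model2"].table["beta"].abs().mean()
        assert b2 < b1
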