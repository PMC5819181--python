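"""Model fits against independent oracles (statsmodels, scipy, algebra)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from nestchoice.stats import (ConditionalLogit, DecisionLogit, PowerNullModel,
                              fit_decision_model, fit_partner_model,
                              fit_power_null, mann_whitney,
                              permutation_mean_diff)


class TestPowerNullModel:
    def test_recovers_true_exponent(self):
        rng = np.random.default_rng(3)
        P = rng.uniform(0.05, 1.0, 4000)
        y = (rng.random(4000) < P ** 1.7).astype(float)
        fit = fit_power_null((P, y))
        assert fit.a == pytest.approx(1.7, abs=0.1)
        assert fit.n == 4000

    def test_matches_independent_sse_minimiser(self):
        rng = np.random.default_rng(8)
        P = rng.uniform(0.05, 1.0, 300)
        y = (rng.random(300) < P).astype(float)

        def sse(a):
            return float(np.sum((y - P ** a) ** 2))

        oracle = scipy.optimize.minimize_scalar(
            sse, bounds=(1e-6, 50.0), method="bounded",
            options={"xatol": 1e-12})
        fit = fit_power_null((P, y))
        assert fit.a == pytest.approx(oracle.x, abs=1e-6)
        assert sse(fit.a) <= sse(oracle.x) + 1e-12

    def test_null_a_test_statistics(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < P).astype(float)
        fit = fit_power_null((P, y))
        assert fit.df == fit.n - 1
        # t and p consistent with each other
        p_from_t = 2 * scipy.stats.t.sf(abs(fit.t), fit.df)
        assert fit.p == pytest.approx(p_from_t, abs=1e-12)

    def test_zero_p_dropped_and_degenerate_errors(self):
        fit = fit_power_null((np.array([0.0, 0.5, 0.5, 1.0, 0.25]),
                              np.array([1, 1, 0, 1, 0])))
        assert fit.n == 4                       # the P=0 event is dropped
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_power_null((np.ones(10), np.ones(10)))
        with pytest.raises(ValueError):
            fit_power_null((np.array([0.5, 1.2]), np.array([0, 1])))


class TestDecisionLogitVsStatsmodels:
    @pytest.fixture(scope="class")
    def data(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(400, 3))
        eta = -0.3 + X @ np.array([0.8, -0.5, 0.2])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        return X, y

    def test_coefficients_match_glm(self, data):
        X, y = data
        ours = DecisionLogit().fit(X, y)
        glm = sm.GLM(y, sm.add_constant(X),
                     family=sm.families.Binomial()).fit()
        assert np.allclose(ours.coef_, glm.params, atol=1e-6)
        assert np.allclose(ours.se_, glm.bse, atol=1e-5)
        assert ours.loglik_ == pytest.approx(glm.llf, abs=1e-6)

    def test_constant_covariate_dropped_with_flag(self, data):
        X, y = data
        Xc = np.column_stack([X, np.full(len(X), 7.0)])
        fit = DecisionLogit().fit(Xc, y, names=["a", "b", "c", "const7"])
        assert any(f.startswith("constant_covariates_dropped") and
                   "const7" in f for f in fit.flags_)
        assert np.isnan(fit.coef_[fit.result_.names.index("const7")])
        assert np.allclose(fit.coef_[:4], DecisionLogit().fit(X, y).coef_,
                           atol=1e-10, equal_nan=True)

    def test_separation_flagged_and_finite(self):
        x = np.linspace(-1, 1, 40)[:, None]
        y = (x[:, 0] > 0).astype(float)        # perfectly separated
        fit = DecisionLogit().fit(x, y)
        assert "separation_penalised_refit" in fit.flags_
        assert np.all(np.isfinite(fit.coef_))


class TestConditionalLogit:
    @staticmethod
    def _simulate(rng, n_events=150, n_opts=2, k=2,
                  beta=np.array([1.0, -0.7])):
        X, groups, chosen = [], [], []
        for g in range(n_events):
            Xe = rng.normal(size=(n_opts, k))
            util = Xe @ beta
            pr = np.exp(util - util.max())
            pr /= pr.sum()
            pick = rng.choice(n_opts, p=pr)
            X.append(Xe)
            groups.extend([g] * n_opts)
            chosen.extend([i == pick for i in range(n_opts)])
        return np.vstack(X), np.array(groups), np.array(chosen)

    def test_two_option_events_equal_paired_logistic(self):
        """With 2 options, conditional logit == logistic on the covariate
        difference with no intercept (exact algebraic identity)."""
        rng = np.random.default_rng(17)
        X, groups, chosen = self._simulate(rng)
        cl = ConditionalLogit().fit(X, groups, chosen)
        diffs = X[0::2] - X[1::2]
        y = chosen[0::2].astype(float)
        paired = DecisionLogit(add_intercept=False).fit(diffs, y)
        assert np.allclose(cl.coef_, paired.coef_, atol=1e-6)
        assert np.allclose(cl.se_, paired.se_, atol=1e-6)
        assert cl.loglik_ == pytest.approx(paired.loglik_, abs=1e-8)

    def test_recovers_truth_three_options(self):
        rng = np.random.default_rng(4)
        X, groups, chosen = self._simulate(rng, n_events=2000, n_opts=3)
        cl = ConditionalLogit().fit(X, groups, chosen)
        assert np.allclose(cl.coef_, [1.0, -0.7], atol=0.12)
        assert cl.converged_

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        X, groups, chosen = self._simulate(rng, n_events=20, n_opts=3)
        cl = ConditionalLogit().fit(X, groups, chosen)
        p = cl.predict_proba()
        assert np.allclose(p.reshape(20, 3).sum(axis=1), 1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="NaN"):
            ConditionalLogit().fit([[np.nan], [0.0]], [0, 0], [True, False])
        with pytest.raises(ValueError, match="exactly one chosen"):
            ConditionalLogit().fit([[1.0], [0.0]], [0, 0], [True, True])


class TestMannWhitney:
    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n, m = rng.integers(2, 8, size=2)
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            W, p = mann_whitney(a, b)
            ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                           method="exact")
            assert W == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_ties_exact_doubled_tail(self):
        a, b = [1, 2, 2], [2, 3]
        W, p = mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact")
        assert W == pytest.approx(ref.statistic)
        assert 0 < p <= 1

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0.8, 1, 70)
        W, p = mann_whitney(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic",
                                       use_continuity=False)
        assert W == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestPermutationMeanDiff:
    def test_detects_clear_shift(self):
        rng = np.random.default_rng(1)
        values = [rng.normal(1.0, 0.1, 4) for _ in range(12)] \
            + [rng.normal(0.0, 0.1, 4) for _ in range(12)]
        labels = [1] * 12 + [0] * 12
        delta, p = permutation_mean_diff(values, labels, n_perm=999, seed=0)
        assert delta == pytest.approx(1.0, abs=0.2)
        assert p < 0.01

    def test_null_p_not_small_and_deterministic(self):
        rng = np.random.default_rng(7)
        values = [rng.normal(0, 1, 3) for _ in range(20)]
        labels = [1, 0] * 10
        d1, p1 = permutation_mean_diff(values, labels, n_perm=500, seed=3)
        d2, p2 = permutation_mean_diff(values, labels, n_perm=500, seed=3)
        assert (d1, p1) == (d2, p2)
        assert p1 > 0.05

    def test_requires_two_events_per_group(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            permutation_mean_diff([np.ones(2), np.ones(2)], [1, 0])


def test_fit_decision_model_scaling_and_names():
    rng = np.random.default_rng(11)
    frame = pd.DataFrame({
        "y": rng.integers(0, 2, 120),
        "n_options": rng.integers(1, 6, 120),
        "n_regular_boxes": rng.integers(2, 8, 120),
        "focal_age": rng.normal(150, 30, 120),
        "experience": rng.integers(0, 2, 120),
        "density": rng.integers(20, 60, 120),
        "summer": rng.integers(0, 2, 120),
    })
    fit = fit_decision_model(frame)
    assert fit.names[0] == "(intercept)"
    assert "n_options" in fit.names
    # binary covariates are left unscaled
    assert "experience" not in fit.scaling and "n_options" in fit.scaling


def test_fit_partner_model_drops_incomplete_events(tenbirth):
    from nestchoice import build_choice_table
    table = build_choice_table(tenbirth, seed=0)
    options = table.option_frame()
    fit = fit_partner_model(options, predictors=["pup_age", "shared_boxes"])
    assert fit.kind == "conditional logit"
    assert fit.n_events >= 2
    # make the chosen option of one event incomplete -> event dropped
    options2 = options.copy()
    chosen_idx = options2.index[options2["chosen"].astype(bool)][0]
    options2.loc[chosen_idx, "pup_age"] = np.nan
    fit2 = fit_partner_model(options2, predictors=["pup_age", "shared_boxes"])
    assert fit2.n_events == fit.n_events - 1
    assert any(f.startswith("dropped_incomplete_events") for f in fit2.flags)
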