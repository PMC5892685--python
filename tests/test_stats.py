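import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from methylsurv.stats import (
    EffectEstimate,
    bh_adjust,
    dersimonian_laird,
    fit_random_intercept_lm,
    pool_rubin,
    spearman_matrix,
)


def est(coef, se, term="x", n=100):
    return EffectEstimate(term=term, coefficient=coef, se=se,
                          ci_low=coef - 1.96 * se, ci_high=coef + 1.96 * se,
                          p_value=0.5, n=n)


class TestRandomInterceptLM:
    def test_single_group_equals_ols(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        df = pd.DataFrame({"x": x})
        groups = pd.Series(["b0"] * n)
        with pytest.warns(UserWarning, match="single group"):
            eff, comps = fit_random_intercept_lm(pd.Series(y), df, groups)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(df)).fit()
        assert eff["x"].coefficient == pytest.approx(ols.params["x"], abs=1e-8)
        assert comps["group_var"] == 0.0

    def test_parameter_recovery_with_batch_intercepts(self):
        rng = np.random.default_rng(5)
        n, n_batches = 1000, 20
        batch = rng.integers(0, n_batches, n)
        intercepts = rng.normal(0, 1.0, n_batches)
        x = rng.normal(size=n)
        y = 2.0 * x + intercepts[batch] + rng.normal(0, 1.0, n)
        eff, comps = fit_random_intercept_lm(
            pd.Series(y), pd.DataFrame({"x": x}), pd.Series(batch)
        )
        assert abs(eff["x"].coefficient - 2.0) < 3 * eff["x"].se
        # compare against the realized variance of the drawn intercepts
        realized = intercepts.var(ddof=1)
        assert abs(comps["group_var"] - realized) / realized < 0.5
        assert abs(comps["resid_var"] - 1.0) / 1.0 < 0.5

    def test_zero_batch_variance_hits_boundary(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        y = x + rng.normal(0, 1.0, n)
        batch = pd.Series(rng.integers(0, 5, n))
        _, comps = fit_random_intercept_lm(pd.Series(y), pd.DataFrame({"x": x}), batch)
        assert comps["group_var"] < 0.05

    def test_singular_design_raises(self, rng):
        n = 100
        x = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="singular"):
            fit_random_intercept_lm(pd.Series(x), df, pd.Series(["a"] * 50 + ["b"] * 50))


class TestRubin:
    def test_hand_example(self):
        pooled = pool_rubin([est(1.0, 1.0), est(2.0, 1.0), est(3.0, 1.0)])
        assert pooled.coefficient == pytest.approx(2.0)
        assert pooled.se**2 == pytest.approx(1 + (4 / 3) * 1.0, abs=1e-10)

    def test_identical_estimates_pass_through(self):
        pooled = pool_rubin([est(1.3, 0.2)] * 4)
        assert pooled.coefficient == pytest.approx(1.3)
        assert pooled.se == pytest.approx(0.2)

    def test_pooled_variance_at_least_within_variance(self, rng):
        for _ in range(20):
            ests = [est(rng.normal(), rng.uniform(0.5, 2)) for _ in range(5)]
            W = np.mean([e.variance for e in ests])
            assert pool_rubin(ests).se**2 >= W - 1e-12

    def test_mismatched_terms_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            pool_rubin([est(1, 1, term="a"), est(1, 1, term="b")])


class TestBH:
    def test_hand_stepup_example(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.04, 0.05])
        assert np.allclose(adj, [0.04, 0.04, 0.05, 0.05])
        assert rej.all()

    def test_single_p_unchanged(self):
        adj, _ = bh_adjust([0.2])
        assert adj[0] == pytest.approx(0.2)

    def test_all_equal_stay_equal(self):
        adj, _ = bh_adjust([0.3] * 7)
        assert np.allclose(adj, 0.3)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=50)
        adj, _ = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bh_adjust([])


class TestDerSimonianLaird:
    def test_identical_estimates(self):
        pooled = dersimonian_laird([est(0.7, 0.1), est(0.7, 0.1)])
        assert pooled.coefficient == pytest.approx(0.7)
        assert pooled.tau2 == 0.0

    def test_hand_example(self):
        pooled = dersimonian_laird([est(0.0, 1.0), est(2.0, 1.0)])
        assert pooled.q_statistic == pytest.approx(2.0)
        assert pooled.tau2 == pytest.approx(1.0)
        assert pooled.coefficient == pytest.approx(1.0)
        assert pooled.se**2 == pytest.approx(1.0)

    def test_zero_tau2_reduces_to_fixed_effect(self):
        ests = [est(1.0, 0.5), est(1.0, 0.25)]
        pooled = dersimonian_laird(ests)
        w = np.array([4.0, 16.0])
        assert pooled.tau2 == 0.0
        assert pooled.coefficient == pytest.approx(1.0)
        assert pooled.se == pytest.approx(np.sqrt(1 / w.sum()))

    def test_pooled_within_input_range(self, rng):
        for _ in range(30):
            ests = [est(rng.normal(), rng.uniform(0.3, 2)) for _ in range(4)]
            pooled = dersimonian_laird(ests)
            coefs = [e.coefficient for e in ests]
            assert min(coefs) - 1e-12 <= pooled.coefficient <= max(coefs) + 1e-12

    def test_matches_statsmodels_combine_effects(self, rng):
        checked = 0
        while checked < 10:
            y = rng.normal(scale=3, size=5)
            v = rng.uniform(0.2, 2, size=5)
            ref = combine_effects(y, v, method_re="dl")
            if ref.tau2 <= 0:  # statsmodels reports the untruncated moment
                continue
            ests = [est(float(a), float(np.sqrt(b))) for a, b in zip(y, v)]
            mine = dersimonian_laird(ests)
            assert mine.tau2 == pytest.approx(ref.tau2, rel=1e-8)
            frame = ref.summary_frame()
            assert mine.coefficient == pytest.approx(
                frame.loc["random effect", "eff"], rel=1e-8
            )
            checked += 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            dersimonian_laird([est(1, 1)])


class TestSpearmanMatrix:
    def test_diagonal_and_self_correlation(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        m = spearman_matrix(df)
        assert np.allclose(np.diag(m), 1.0)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "ex": np.exp(x)})
        m = spearman_matrix(df)
        assert m.loc["x", "ex"] == pytest.approx(1.0)

    def test_constant_column_flagged(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20), "c": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            m = spearman_matrix(df)
        assert np.isnan(m.loc["x", "c"])

    def test_indicator_correlation_pattern_on_synthetic_cohort(self, sim5000):
        from methylsurv.scores import build_score_panel

        panel = build_score_panel(
            sim5000.cohort, sim5000.betas, fi=sim5000.cohort["fi_true"]
        )
        m = spearman_matrix(
            panel[["mrscore", "cont_mrscore", "age_acceleration", "fi"]]
        )
        assert abs(m.loc["age_acceleration", "fi"]) < 0.2
        assert m.loc["mrscore", "cont_mrscore"] > 0.6
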