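import numpy as np
import pandas as pd
import pytest

from methylsurv.simulate import SimulationConfig, sample_case_cohort, simulate_cohort
from methylsurv.survival import (
    fit_case_cohort_cox,
    fit_cox,
    fit_logistic,
    rescale_effect,
    rescale_hr,
)


def toy_cox_frame():
    return pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 1, 1], "x": [1.0, 0.0, 1.0]})


def efron_free_logpl(beta):
    """Log partial likelihood of the 3-subject toy (no ties, so exact)."""
    u = np.exp(beta)
    return np.log(u / (2 * u + 1)) + np.log(1 / (1 + u))


class TestCox:
    def test_toy_matches_analytic_maximum(self):
        fit = fit_cox(toy_cox_frame(), "time", "event", ["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(-0.5 * np.log(2), abs=1e-6)

    def test_partial_likelihood_improves_over_null(self):
        fit = fit_cox(toy_cox_frame(), "time", "event", ["x"])
        beta = fit.summary.loc["x", "coef"]
        assert efron_free_logpl(beta) >= efron_free_logpl(0.0)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(0)
        n = 2000
        df = pd.DataFrame({
            "time": rng.exponential(10, n),
            "event": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
        })
        fit = fit_cox(df, "time", "event", ["x"])
        assert abs(fit.summary.loc["x", "coef"]) < 3 * fit.summary.loc["x", "se"]

    def test_unit_weights_equal_unweighted(self):
        df = toy_cox_frame().assign(w=1.0)
        a = fit_cox(df, "time", "event", ["x"])
        b = fit_cox(df, "time", "event", ["x"], weights_col="w")
        assert a.summary.loc["x", "coef"] == pytest.approx(b.summary.loc["x", "coef"], abs=1e-10)

    def test_constant_weight_scaling_leaves_coef(self):
        rng = np.random.default_rng(1)
        n = 300
        df = pd.DataFrame({
            "time": rng.exponential(5, n), "event": rng.integers(0, 2, n),
            "x": rng.normal(size=n), "w": 1.0,
        })
        a = fit_cox(df, "time", "event", ["x"], weights_col="w")
        df["w"] = 3.0
        b = fit_cox(df, "time", "event", ["x"], weights_col="w")
        assert a.summary.loc["x", "coef"] == pytest.approx(b.summary.loc["x", "coef"], abs=1e-8)

    def test_no_events_rejected(self):
        df = toy_cox_frame().assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, "time", "event", ["x"])

    def test_collinear_covariates_rejected(self):
        df = toy_cox_frame().assign(x2=lambda d: 2 * d["x"])
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(df, "time", "event", ["x", "x2"])


class TestCaseCohortCox:
    def test_full_subcohort_equals_plain_cox(self, sim1000):
        cc = sample_case_cohort(sim1000, subcohort_fraction=1.0, seed=5)
        data = cc.cohort.assign(x=cc.betas.loc["cg06126421"].to_numpy())
        full_fit = fit_cox(data, "time", "event", ["x"])
        cc_fit = fit_case_cohort_cox(data, "time", "event", ["x"],
                                     sampling_fraction=1.0)
        assert cc_fit.summary.loc["x", "coef"] == pytest.approx(
            full_fit.summary.loc["x", "coef"], abs=1e-4
        )

    def test_recovers_true_effect_single_replicate(self):
        cfg = SimulationConfig(
            n_subjects=3000, seed=21,
            log_hr_per_sd=(np.log(2), 0.0, 0.0), log_hr_per_year_age=0.0,
        )
        full = simulate_cohort(cfg)
        from methylsurv.scores import cont_mrscore, zscore

        score_z = zscore(cont_mrscore(full.betas))
        cc = sample_case_cohort(full, subcohort_fraction=0.25, seed=22)
        data = cc.cohort.assign(score_z=score_z.loc[cc.subjects])
        fit = fit_case_cohort_cox(data, "time", "event", ["score_z"],
                                  sampling_fraction=0.25)
        coef = fit.summary.loc["score_z", "coef"]
        se = fit.summary.loc["score_z", "se"]
        assert abs(coef - np.log(2)) < 3 * se

    def test_robust_se_reported_with_weights(self, sim1000):
        cc = sample_case_cohort(sim1000, subcohort_fraction=0.3, seed=2)
        data = cc.cohort.assign(x=cc.betas.loc["cg06126421"].to_numpy())
        fit = fit_case_cohort_cox(data, "time", "event", ["x"],
                                  sampling_fraction=0.3)
        assert fit.weighted
        assert np.isfinite(fit.summary.loc["x", "se"])

    def test_missing_design_information_rejected(self, sim1000):
        data = sim1000.cohort.assign(x=1.0)
        with pytest.raises((ValueError, KeyError)):
            fit_case_cohort_cox(data, "time", "event", ["x"], subcohort_col="nope")


class TestLogistic:
    @staticmethod
    def two_by_two(a, b, c, d):
        """Exposed/unexposed x case/control counts -> long frame."""
        rows = ([(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d)
        return pd.DataFrame(rows, columns=["x", "y"])

    def test_balanced_table_gives_null_or(self):
        fit = fit_logistic(self.two_by_two(10, 10, 10, 10), "y", ["x"])
        assert fit.summary.loc["x", "coef"] == pytest.approx(0.0, abs=1e-8)

    def test_cross_product_ratio(self):
        fit = fit_logistic(self.two_by_two(20, 10, 10, 20), "y", ["x"])
        assert fit.summary.loc["x", "hr"] == pytest.approx(4.0, rel=1e-6)

    def test_duplicate_column_rank_error(self):
        df = self.two_by_two(10, 10, 10, 10).assign(x2=lambda d: d["x"])
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(df, "y", ["x", "x2"])

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "y": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        with pytest.raises(RuntimeError, match="separation|converge"):
            fit_logistic(df, "y", ["x"])


class TestRescaling:
    def test_null_hr_invariant(self):
        assert rescale_hr(1.0, 1.0, 1.0, 3.7) == (1.0, 1.0, 1.0)

    def test_hand_exponentiation(self):
        hr, _, _ = rescale_hr(2.0, 1.5, 2.5, 0.5)
        assert hr == pytest.approx(np.sqrt(2))

    def test_fit_interface_round_trip(self):
        fit = fit_cox(toy_cox_frame(), "time", "event", ["x"])
        out = rescale_effect(fit, "x", to_unit=2.0)
        assert out["hr"] == pytest.approx(fit.summary.loc["x", "hr"] ** 2)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rescale_hr(2.0, 1.0, 3.0, 0.0)


def test_category_hazard_ordering_on_synthetic_cohort(sim5000):
    """Categorized score fits show the monotone risk ladder (1 < 2-5 < >5)."""
    from methylsurv.scores import build_score_panel

    panel = build_score_panel(sim5000.cohort, sim5000.betas, fi=sim5000.cohort["fi_true"])
    data = sim5000.cohort.join(panel[["mrscore_category"]])
    for cat, col in (("1", "c1"), ("2-5", "c25"), (">5", "c5p")):
        data[col] = (data["mrscore_category"] == cat).astype(float)
    fit = fit_cox(data, "time", "event", ["c1", "c25", "c5p", "age", "sex"])
    hrs = fit.summary.loc[["c1", "c25", "c5p"], "hr"].to_numpy()
    assert hrs[0] < hrs[1] < hrs[2]
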