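import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from condgrowth.errors import EstimationError
from condgrowth.risk import DelayRiskModel, ModelSpec, exposure_names, fit_rr_model, format_table, run_model_grid


def _binary_data():
    """20 rows, one binary exposure: 4/10 events among exposed, 2/10 among
    unexposed -> closed-form risk ratio 2.0."""
    exposed = [1] * 10 + [0] * 10
    outcome = [1] * 4 + [0] * 6 + [1] * 2 + [0] * 8
    return pd.DataFrame({"x": exposed, "y": outcome})


class TestDelayRiskModel:
    def test_single_binary_regressor_equals_risk_ratio(self):
        res = DelayRiskModel(_binary_data(), "y", ["x"], covariates=()).fit()
        assert res.arr["x"] == pytest.approx((4 / 10) / (2 / 10), abs=1e-10)
        assert res.events == 6 and res.n_used == 20

    def test_point_estimates_equal_poisson_mle(self):
        """Quasi-Poisson scaling must not move the coefficients: compare
        against an independently optimized Poisson maximum likelihood."""
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.standard_normal(n)
        w = rng.standard_normal(n)
        p = 0.1 * np.exp(0.2 * x - 0.1 * w)
        y = rng.random(n) < p
        df = pd.DataFrame({"x": x, "w": w, "y": y.astype(int)})
        res = DelayRiskModel(df, "y", ["x", "w"], covariates=()).fit()
        X = sm.add_constant(df[["x", "w"]].to_numpy())
        mle = sm.Poisson(df["y"].to_numpy(), X).fit(disp=0, method="newton")
        assert np.allclose(res.params.to_numpy(), mle.params, atol=1e-8)

    def test_ci_width_scales_with_sqrt_dispersion(self):
        df = _binary_data()
        res = DelayRiskModel(df, "y", ["x"], covariates=()).fit()
        glm = sm.GLM(df["y"].to_numpy(), sm.add_constant(df[["x"]].to_numpy()), family=sm.families.Poisson())
        unscaled = glm.fit()
        ratio = res.bse.to_numpy() / unscaled.bse
        assert np.allclose(ratio, np.sqrt(res.dispersion), atol=1e-10)
        assert res.dispersion > 0

    def test_complete_case_dropping_is_logged(self):
        df = _binary_data()
        df.loc[0, "x"] = np.nan
        model = DelayRiskModel(df, "y", ["x"], covariates=())
        assert model.n_dropped == 1 and len(model.data) == 19

    def test_non_binary_outcome_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "y": [0, 1, 2, 1]})
        with pytest.raises(ValueError, match="binary"):
            DelayRiskModel(df, "y", ["x"], covariates=())

    def test_rank_deficiency_raises(self):
        df = _binary_data()
        df["x2"] = df["x"]
        with pytest.raises(EstimationError):
            DelayRiskModel(df, "y", ["x", "x2"], covariates=()).fit()

    def test_summary_and_rr_invariants(self, small_analysis):
        analysis = small_analysis["analysis"]
        boys = analysis[analysis["sex"] == "boy"]
        from condgrowth.conditional import ConditionalGrowthModel

        cg = ConditionalGrowthModel(boys, variant="birth4").fit()
        merged = cg.conditionals.join(boys[[c for c in boys.columns if c not in cg.conditionals.columns]])
        res = DelayRiskModel(merged, "delayed_6_total", exposure_names("birth4")).fit()
        for rr in res.results_for():
            assert 0 < rr.ci_low <= rr.aRR <= rr.ci_high
            assert rr.dispersion > 0
            assert rr.events <= rr.n_used


class TestRunModelGrid:
    @pytest.fixture(scope="class")
    def tables(self, small_analysis):
        return run_model_grid(small_analysis["analysis"])

    def test_grid_shape(self, tables):
        assert len(tables) == 8  # 2 sexes x (6-month + three 12-month variants)
        for (sex, label), tidy in tables.items():
            assert set(tidy["outcome"]) == {"total", "Communication", "GrossMotor", "FineMotor", "ProblemSolving", "PersonalSocial"}

    def test_model2_has_no_ten_month_terms(self, tables):
        terms = set(tables[("boy", "12mo_model2")]["term"])
        assert terms == {"length0", "weight0", "cLength4", "crWeight4", "cLength7", "crWeight7"}

    def test_events_rates_match_configured_baselines(self, tables, small_cohort):
        """Per-column events/n on the default cohort approximate the
        configured sex-specific delay rates (the configured true RRs tilt
        them only mildly)."""
        for sex in ("boy", "girl"):
            tidy = tables[(sex, "6mo")]
            row = tidy[tidy["outcome"] == "total"].iloc[0]
            rate = row["events"] / row["n_used"]
            target = small_cohort.config.baseline_delay_prob[(6, sex)]
            assert abs(rate - target) < 0.02

    def test_formatted_table_layout(self, tables):
        formatted = format_table(tables[("girl", "6mo")])
        assert formatted.index[0] == "events/n"
        cell = formatted.loc["cLength4", "total"]
        assert "(" in cell and "–" in cell

    def test_fit_rr_model_wrapper(self, small_analysis):
        analysis = small_analysis["analysis"]
        boys = analysis[analysis["sex"] == "boy"]
        from condgrowth.conditional import ConditionalGrowthModel

        cg = ConditionalGrowthModel(boys, variant="birth4").fit()
        merged = cg.conditionals.join(boys[[c for c in boys.columns if c not in cg.conditionals.columns]])
        spec = ModelSpec(outcome="delayed_6_total", exposures=tuple(exposure_names("birth4")))
        results = fit_rr_model(merged, spec)
        assert [r.term for r in results] == ["length0", "weight0", "cLength4", "crWeight4"]


class TestCoverage:
    def test_null_cis_cover_one(self, null_runs):
        """With every true RR = 1: the headline exposure's CI covers 1 in
        >= 18/20 seeded pipeline runs, and pooled coverage across all four
        exposures stays >= 90% (per-term 18/20 at nominal 95% would fail by
        binomial chance alone ~7.5% of the time per term)."""
        terms = ("length0", "weight0", "cLength4", "crWeight4")
        per_term = {
            term: sum(1 for run in null_runs if run[term][1] <= 1.0 <= run[term][2]) for term in terms
        }
        assert per_term["cLength4"] >= 18, per_term
        assert sum(per_term.values()) >= 0.9 * 20 * len(terms), per_term

    def test_ci_calibration_under_true_effect(self, recovery_runs):
        """With a true cLength4 effect of 0.85 (others null), per-exposure
        coverage of the truth stays >= 0.85 across 20 seeds."""
        truth = {"length0": 1.0, "weight0": 1.0, "cLength4": 0.85, "crWeight4": 1.0}
        for term, t in truth.items():
            covered = sum(1 for run in recovery_runs if run[term][1] <= t <= run[term][2])
            assert covered >= 17, f"{term}: {covered}/20"
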