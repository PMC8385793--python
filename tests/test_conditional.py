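import numpy as np
import pandas as pd
import pytest

from condgrowth.conditional import (
    VARIANT_TIMEPOINTS,
    ConditionalGrowthModel,
    build_conditional_set,
    conditional_length,
    conditional_relative_weight,
)
from condgrowth.errors import EstimationError


def normal_equations_residuals(y, X):
    """Independent oracle: OLS residuals via explicit normal equations."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta


def standardized(r):
    return r / r.std(ddof=1)


def _zframe(rng, n, months=(0, 4, 7, 10)):
    cols = {}
    base = rng.standard_normal(n)
    for t in months:
        for m in ("length", "weight"):
            cols[f"z_{m}_{t}"] = 0.6 * base + 0.8 * rng.standard_normal(n)
    return pd.DataFrame(cols)


class TestConditionalLength:
    def test_hand_five_row_simple_regression(self):
        current = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        prev = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        got = conditional_length(current, [prev])
        expect = standardized(normal_equations_residuals(current, prev[:, None]))
        assert np.allclose(got, expect, atol=1e-9)

    def test_perfect_fit_degenerates_to_zero_with_warning(self):
        prev = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0])
        with pytest.warns(UserWarning, match="degenerate"):
            got = conditional_length(2.0 * prev + 1.0, [prev])
        assert np.allclose(got, 0.0)

    def test_orthogonal_to_regressors(self):
        rng = np.random.default_rng(5)
        z = _zframe(rng, 2000, months=(0, 4))
        resid = conditional_length(
            z["z_length_4"].to_numpy(), [z["z_length_0"].to_numpy(), z["z_weight_0"].to_numpy()]
        )
        for col in ("z_length_0", "z_weight_0"):
            assert abs(np.corrcoef(resid, z[col])[0, 1]) < 1e-8


class TestConditionalRelativeWeight:
    def test_weight_linear_in_length_gives_zero(self):
        rng = np.random.default_rng(1)
        length = rng.standard_normal(50)
        prev = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="degenerate"):
            got = conditional_relative_weight(3.0 * length - 1.0, length, [prev])
        assert np.allclose(got, 0.0)

    def test_hand_six_rows_vs_normal_equations(self):
        y = np.array([2.1, 1.3, 0.2, -0.5, 1.8, -1.2])
        cl = np.array([1.0, 0.5, -0.3, -1.0, 0.9, -1.5])
        p1 = np.array([0.2, -0.1, 0.7, 0.3, -0.6, 0.1])
        got = conditional_relative_weight(y, cl, [p1])
        expect = standardized(normal_equations_residuals(y, np.column_stack([cl, p1])))
        assert np.allclose(got, expect, atol=1e-9)

    def test_orthogonal_to_conditional_length(self):
        rng = np.random.default_rng(9)
        z = _zframe(rng, 3000, months=(0, 4))
        cset = build_conditional_set(z, "birth4")
        assert abs(np.corrcoef(cset["crWeight4"], cset["cLength4"])[0, 1]) < 1e-8


class TestBuildConditionalSet:
    def test_variant_2_emits_no_10_month_terms(self):
        rng = np.random.default_rng(3)
        z = _zframe(rng, 200)
        cset = build_conditional_set(z, 2)
        assert list(cset.columns) == ["length0", "weight0", "cLength4", "crWeight4", "cLength7", "crWeight7"]

    def test_variant_3_skips_seven_months_in_regressors(self):
        """Variant 3's 10-month conditionals regress on birth + 4 months
        only, so they differ from variant 1's even on identical data."""
        rng = np.random.default_rng(4)
        z = _zframe(rng, 500)
        c1 = build_conditional_set(z, 1)
        c3 = build_conditional_set(z, 3)
        assert "cLength7" not in c3.columns
        assert not np.allclose(c1["cLength10"], c3["cLength10"])
        # but the variables shared up to 4 months agree
        assert np.allclose(c1["cLength4"], c3["cLength4"], atol=1e-12)

    def test_identical_children_raise_estimation_error(self):
        z = pd.DataFrame({c: np.ones(30) for c in [f"z_{m}_{t}" for t in (0, 4) for m in ("length", "weight")]})
        with pytest.raises(EstimationError):
            build_conditional_set(z, "birth4")

    def test_all_pairwise_correlations_vanish_variant_1(self):
        """The six post-birth conditionals are mutually orthogonal and
        orthogonal to both birth sizes; only length0-weight0 (raw birth
        z-scores, nothing residualized out) may correlate."""
        rng = np.random.default_rng(11)
        z = _zframe(rng, 5000)
        cset = build_conditional_set(z, 1)
        corr = cset.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr[0, 1] = corr[1, 0] = 0.0  # length0 vs weight0
        assert np.abs(corr).max() < 1e-6

    def test_mean_zero_unit_variance(self):
        rng = np.random.default_rng(12)
        cset = build_conditional_set(_zframe(rng, 1000), 1)
        assert np.abs(cset.mean().to_numpy()).max() < 1e-8
        assert np.allclose(cset.std(ddof=1).to_numpy(), 1.0, atol=1e-8)

    def test_scale_invariance_of_standardized_conditionals(self):
        rng = np.random.default_rng(13)
        z = _zframe(rng, 400)
        c1 = build_conditional_set(z, 1)
        c2 = build_conditional_set(z * 3.7, 1)
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("n_rows", [20, 35, 50])
    def test_oracle_equivalence_small_samples(self, n_rows):
        """Residuals match a brute-force normal-equations solve on <=50 rows."""
        rng = np.random.default_rng(n_rows)
        z = _zframe(rng, n_rows)
        cset = build_conditional_set(z, 1)
        regressors = {
            "cLength4": ("z_length_4", ["z_length_0", "z_weight_0"]),
            "crWeight4": ("z_weight_4", ["z_length_4", "z_length_0", "z_weight_0"]),
            "cLength7": ("z_length_7", ["z_length_0", "z_weight_0", "z_length_4", "z_weight_4"]),
            "crWeight10": (
                "z_weight_10",
                ["z_length_10", "z_length_0", "z_weight_0", "z_length_4", "z_weight_4", "z_length_7", "z_weight_7"],
            ),
        }
        for name, (ycol, xcols) in regressors.items():
            expect = standardized(normal_equations_residuals(z[ycol], z[xcols].to_numpy()))
            assert np.allclose(cset[name].to_numpy(), expect, atol=1e-9)

    def test_missing_rows_rejected(self):
        rng = np.random.default_rng(2)
        z = _zframe(rng, 50)
        z.loc[3, "z_length_4"] = np.nan
        with pytest.raises(ValueError, match="complete cases"):
            build_conditional_set(z, "birth4")


class TestConditionalGrowthModel:
    def test_model_drops_incomplete_rows_and_summarizes(self):
        rng = np.random.default_rng(8)
        z = _zframe(rng, 300)
        z.loc[:9, "z_weight_7"] = np.nan
        res = ConditionalGrowthModel(z, variant=1, sex="boy").fit()
        assert res.n_obs == 290
        summary = res.summary()
        assert summary["mean"].abs().max() < 1e-8
        assert summary.loc[["cLength4", "crWeight4", "cLength7", "crWeight7"], "max_abs_corr"].max() < 1e-6
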