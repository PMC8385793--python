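import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condgrowth import lms_inverse, lms_zscore, simulate_cohort, synthetic_reference, zscore_child
from condgrowth.reference import GrowthReference
from condgrowth.simulate import MissingnessConfig, default_config
from condgrowth.timeline import timeline_frame
from condgrowth.reference import zscore_frame


class TestLMSTransform:
    @pytest.mark.parametrize(
        "x,L,M,S,expected",
        [
            (3000.0, 0.7, 3000.0, 0.12, 0.0),  # the median maps to zero
            (3360.0, 1.0, 3000.0, 0.12, 1.0),  # L=1: (x-M)/(M*S)
            (50.0 * np.exp(0.08), 0.0, 50.0, 0.04, 2.0),  # L=0: ln(x/M)/S
        ],
    )
    def test_closed_forms(self, x, L, M, S, expected):
        assert lms_zscore(x, L, M, S) == pytest.approx(expected, abs=1e-12)

    def test_inverse_closed_form(self):
        assert lms_inverse(1.0, 1.0, 3000.0, 0.12) == pytest.approx(3360.0)
        assert lms_inverse(0.0, 0.42, 61.2, 0.04) == pytest.approx(61.2)

    @given(
        z=st.floats(-4, 4),
        L=st.floats(-2, 2),
        S=st.floats(0.01, 0.2),
        M=st.floats(1.0, 10000.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_round_trip(self, z, L, M, S):
        if abs(L) > 1e-7 and 1 + L * S * z <= 1e-6:
            return  # outside the invertible range
        x = lms_inverse(z, L, M, S)
        assert lms_zscore(x, L, M, S) == pytest.approx(z, abs=1e-10)

    @given(L=st.floats(-2, 2), S=st.floats(0.01, 0.2))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_x(self, L, S):
        xs = np.linspace(0.5, 2.0, 25) * 100.0
        zs = lms_zscore(xs, L, 100.0, S)
        assert np.all(np.diff(zs) > 0)

    def test_continuity_in_L_at_zero(self):
        xs = np.linspace(40.0, 70.0, 31)
        z_small = lms_zscore(xs, 1e-8, 50.0, 0.04)
        z_zero = lms_zscore(xs, 0.0, 50.0, 0.04)
        assert np.max(np.abs(z_small - z_zero)) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            lms_zscore(-1.0, 1.0, 50.0, 0.04)
        with pytest.raises(ValueError):
            lms_zscore(50.0, 1.0, 0.0, 0.04)
        with pytest.raises(ValueError):
            lms_inverse(-100.0, 1.0, 50.0, 0.04)  # 1 + LSz < 0


class TestGrowthReference:
    def test_csv_round_trip(self, tmp_path):
        ref = synthetic_reference()
        path = tmp_path / "ref.csv"
        ref.to_csv(path)
        ref2 = GrowthReference.from_csv(path)
        for age in (0, 122, 213, 304):
            kw = {"parity": "primipara", "gestational_week": 39} if age == 0 else {}
            assert ref.lookup("boy", "weight", age, **kw) == pytest.approx(ref2.lookup("boy", "weight", age, **kw))

    def test_nearest_within_tolerance_else_interpolated(self):
        ref = synthetic_reference()
        exact = ref.lookup("girl", "length", 122)
        assert ref.lookup("girl", "length", 130) == pytest.approx(exact)  # within 15 d
        # sparse table: a query 50 d from both rows interpolates L, M, S
        sparse = GrowthReference(
            pd.DataFrame(
                {
                    "sex": ["boy", "boy"],
                    "measure": ["weight", "weight"],
                    "age_days": [100, 200],
                    "parity": ["any", "any"],
                    "gestational_week": ["any", "any"],
                    "L": [0.4, 0.2],
                    "M": [6000.0, 8000.0],
                    "S": [0.10, 0.12],
                }
            )
        )
        L, M, S = sparse.lookup("boy", "weight", 150)
        assert (L, M, S) == pytest.approx((0.3, 7000.0, 0.11))

    def test_missing_stratum_is_a_lookup_error(self):
        ref = synthetic_reference()
        with pytest.raises(KeyError, match="gestational_week"):
            ref.lookup("boy", "weight", 0, "primipara", 45)

    def test_stratification_disallowed_after_birth(self):
        table = synthetic_reference().table.copy()
        bad = table.iloc[[0]].assign(age_days=100)
        with pytest.raises(ValueError):
            GrowthReference(pd.concat([table, bad], ignore_index=True))


class TestZscoreChild:
    def test_median_child_scores_zero(self):
        ref = synthetic_reference()
        vals = {}
        for age in (0, 122):
            if age == 0:
                _, ml, _ = ref.lookup("boy", "length", 0, "multipara", 38)
                _, mw, _ = ref.lookup("boy", "weight", 0, "multipara", 38)
            else:
                _, ml, _ = ref.lookup("boy", "length", age)
                _, mw, _ = ref.lookup("boy", "weight", age)
            vals[age] = (ml, mw)
        z = zscore_child("boy", "multipara", 38.4, vals, ref)
        for age in vals:
            assert z[age][0] == pytest.approx(0.0, abs=1e-12)
            assert z[age][1] == pytest.approx(0.0, abs=1e-12)

    def test_parity_stratum_changes_birth_z(self):
        ref = synthetic_reference()
        z1 = zscore_child("girl", "primipara", 39.0, {0: (48.8, 3000.0)}, ref)
        z2 = zscore_child("girl", "multipara", 39.0, {0: (48.8, 3000.0)}, ref)
        assert z1[0][1] != z2[0][1]

    def test_absent_inputs_yield_absent_outputs(self):
        ref = synthetic_reference()
        z = zscore_child("boy", "primipara", 40.0, {122: (None, 7000.0)}, ref)
        assert z[122][0] is None and z[122][1] is not None


class TestSimulatorRoundTrip:
    def test_latent_z_recovered_through_pipeline(self):
        """With checkups at exact target ages and no missingness, the
        timeline + z-score stages reproduce the generator's latent z-scores
        (up to raw-value rounding: 0.1 cm / 1 g)."""
        cfg = default_config(
            n_children=300,
            checkup_jitter_days=0,
            missingness=MissingnessConfig(
                checkup={4: 0.0, 7: 0.0, 10: 0.0}, asq={6: 0.0, 12: 0.0}, item_prob=0.0,
                covariate={}, p_missing_basic=0.0,
            ),
            p_malformation=0.0,
            p_multiple_birth=0.0,
        )
        ref = synthetic_reference()
        cohort = simulate_cohort(cfg, ref=ref, seed=11)
        x = timeline_frame(cohort.data)
        z = zscore_frame(cohort.data, x, ref)
        for measure, month, col in (("length", 0, "z_length_0"), ("weight", 4, "z_weight_4"), ("length", 10, "z_length_10")):
            latent = cohort.latent_z[f"z_{measure}_{month}"].to_numpy()
            assert np.allclose(z[col].to_numpy(), latent, atol=0.05)
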