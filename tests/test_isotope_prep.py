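import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allomix.isotope_prep import (
    ConsumerPreprocessor,
    MissingBaselineError,
    TrophicConfig,
    corrected_sd,
    estimate_trophic_level,
    fit_baseline_regression,
    fix_methane_influenced,
    impute_missing_baselines,
    omega_compound,
    omega_correct,
)
from .conftest import model_data_from, small_config
from allomix.synthetic import generate_dataset


class TestTrophicLevel:
    @pytest.mark.parametrize(
        "consumer, baseline, expected",
        [
            (6.0, 6.0, 2.1),       # zero enrichment -> baseline level
            (9.4, 6.0, 3.1),       # one TDF step
            (10.0, 4.9, 3.6),      # 2.1 + 5.1/3.4
        ],
    )
    def test_single_end_member_model(self, consumer, baseline, expected):
        assert estimate_trophic_level(consumer, baseline) == pytest.approx(expected)

    def test_sub_source_levels_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            tl = estimate_trophic_level(0.0, 10.0)
        assert tl == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-20, 20), st.floats(-10, 10), st.floats(-5, 5))
    def test_invariant_to_common_baseline_shift(self, c, b, shift):
        t0 = estimate_trophic_level(c, b)
        t1 = estimate_trophic_level(c + shift, b + shift)
        assert t0 == pytest.approx(t1, abs=1e-9)


class TestBaselineRegression:
    def test_perfect_linear_relation(self):
        x = np.arange(5.0)
        slope, intercept, adj_r2 = fit_baseline_regression(x, 2 * x + 1)
        assert (slope, intercept) == pytest.approx((2.0, 1.0))
        assert adj_r2 == pytest.approx(1.0)

    def test_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(2, 12, 30)
        y = 0.9 * x - 0.5 + rng.normal(0, 0.3, 30)
        slope, intercept, adj_r2 = fit_baseline_regression(x, y)
        assert slope == pytest.approx(0.9, abs=0.1)
        assert adj_r2 > 0.9

    def test_insufficient_lakes(self):
        with pytest.raises(ValueError, match="3"):
            fit_baseline_regression([1.0, 2.0], [1.0, 2.0])

    def test_constant_predictor(self):
        with pytest.raises(ValueError, match="variance"):
            fit_baseline_regression([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


class TestImputation:
    def test_measured_baselines_kept(self):
        out = impute_missing_baselines(
            {"A": 5.0, "B": 6.0}, {}, (0.872, -0.095)
        )
        assert not out["imputed"].any()
        assert list(out["d15n_baseline"]) == [5.0, 6.0]

    def test_missing_lake_imputed_from_surrogate(self):
        # published-style coefficients: 0.872 * 8.0 - 0.095
        out = impute_missing_baselines(
            {"A": 5.0, "B": None}, {"B": 8.0}, (0.872, -0.095)
        )
        rec = out.set_index("lake_id").loc["B"]
        assert rec["d15n_baseline"] == pytest.approx(6.881)
        assert bool(rec["imputed"])

    def test_unimputable_lake_raises(self):
        with pytest.raises(MissingBaselineError, match="B"):
            impute_missing_baselines({"B": None}, {}, (1.0, 0.0))


class TestMethaneRule:
    def test_depleted_carbon_fixes_tl(self):
        df = pd.DataFrame({"tl": [3.5, 3.0], "d13c": [-40.1, -25.0]})
        out = fix_methane_influenced(df)
        assert out["tl"].tolist() == [2.1, 3.0]
        assert out["methane_fixed"].tolist() == [True, False]

    def test_absent_carbon_column_is_noop(self):
        df = pd.DataFrame({"tl": [3.5]})
        out = fix_methane_influenced(df)
        assert out["tl"].tolist() == [3.5]
        assert not out["methane_fixed"].any()


class TestOmegaCompound:
    @pytest.mark.parametrize(
        "omega, tl, pct",
        [
            (0.14, 3.0, 26),
            (0.23, 3.0, 41),
            (0.32, 3.0, 54),
            (0.14, 4.0, 36),
            (0.32, 4.0, 69),
        ],
    )
    def test_worked_percentages(self, omega, tl, pct):
        assert round(100 * omega_compound(omega, tl)) == pct

    def test_single_step_and_source_level(self):
        assert omega_compound(0.23, 2.0) == pytest.approx(0.23)
        assert omega_compound(0.5, 1.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            omega_compound(1.0, 2.0)
        with pytest.raises(ValueError):
            omega_compound(0.2, 0.5)

    @settings(deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 0.9), st.floats(0.01, 0.9),
        st.floats(1.0, 5.0), st.floats(1.0, 5.0),
    )
    def test_monotone_in_omega_and_tl(self, w1, w2, t1, t2):
        lo_w, hi_w = sorted((w1, w2))
        lo_t, hi_t = sorted((t1, t2))
        assert omega_compound(lo_w, hi_t) <= omega_compound(hi_w, hi_t)
        assert omega_compound(hi_w, lo_t) <= omega_compound(hi_w, hi_t)
        assert 0.0 <= omega_compound(hi_w, hi_t) < 1.0


class TestOmegaCorrect:
    def test_zero_exchange_is_identity(self):
        assert omega_correct(-150.0, -60.0, 0.0) == -150.0

    def test_water_is_fixed_point(self):
        for oc in (0.1, 0.5, 0.9):
            assert omega_correct(-60.0, -60.0, oc) == pytest.approx(-60.0)

    def test_worked_example(self):
        # (-150 + 0.23*60) / 0.77
        assert omega_correct(-150.0, -60.0, 0.23) == pytest.approx(-176.883, abs=1e-3)

    def test_linear_with_amplified_deviation(self):
        oc = 0.4
        d1 = omega_correct(-100.0, -60.0, oc) - (-60.0)
        assert d1 == pytest.approx((-100.0 + 60.0) / (1 - oc))

    def test_rejects_full_exchange(self):
        with pytest.raises(ValueError):
            omega_correct(-100.0, -60.0, 1.0)


def test_corrected_sd_passthrough():
    assert corrected_sd() == 13.0
    assert corrected_sd(TrophicConfig(extra_consumer_sd=0.0)) == 0.0
    assert corrected_sd(TrophicConfig(extra_consumer_sd=20.0)) == 20.0


class TestPreprocessorPipeline:
    def test_composition_identity_forward_then_correct(self):
        """Noise-free forward simulation followed by omega correction returns
        the mixture mean to machine precision for every sample."""
        cfg = small_config(residual_sd=0.0, d15n_noise_sd=0.0)
        ds = generate_dataset(cfg)
        data = model_data_from(ds)
        truth = ds["truth"].observations.set_index("obs_id")
        merged = data.set_index("obs_id").join(truth, rsuffix="_true")
        np.testing.assert_allclose(
            merged["d2h_corrected"], merged["mixture_mean"], atol=1e-9
        )

    def test_baseline_resolution_and_flags(self, small_model_data):
        d = small_model_data
        assert {"tl", "omega_compound", "d2h_corrected", "d2h_corrected_sd"} <= set(d.columns)
        assert (d["d2h_corrected_sd"] == 13.0).all()
        assert (d["omega_compound"] >= 0).all() and (d["omega_compound"] < 1).all()
        # baseline taxa should land near their assigned level
        base = d[d["taxon"] == "cladocera"]["tl"]
        assert base.mean() == pytest.approx(2.1, abs=0.15)

    def test_missing_compartment_baseline_raises(self):
        cons = pd.DataFrame(
            {
                "lake_id": ["L1"] * 2,
                "taxon": ["fish_x"] * 2,
                "group": ["fish"] * 2,
                "d2h": [-150.0, -140.0],
                "d15n": [9.0, 9.5],
                "d2h_water": [-60.0] * 2,
            }
        )
        with pytest.raises(MissingBaselineError):
            ConsumerPreprocessor().fit(cons)
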