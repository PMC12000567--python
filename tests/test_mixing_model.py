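import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allomix.ilr import ilr_inverse
from allomix.mixing_model import (
    AllochthonyMixingModel,
    MixingModelConfig,
    compare_models,
)
from .conftest import model_data_from, small_config
from allomix.synthetic import GeneratorConfig, TaxonSpec, generate_dataset

REDUCED = dict(covariate="none", include_random_effects=False, fix_xi=1.0)


def _fit_small(seed=7, **cfg_kw):
    kw = dict(chains=2, iterations=800, burn_in=500, thinning=5, seed=seed)
    kw.update(cfg_kw)
    ds = generate_dataset(small_config())
    data = model_data_from(ds)
    model = AllochthonyMixingModel(MixingModelConfig(covariate="pc1", **kw)).fit(data)
    return model, data


class TestConfig:
    def test_burn_in_must_precede_end(self):
        with pytest.raises(ValueError):
            MixingModelConfig(iterations=100, burn_in=100)

    def test_paper_scale_settings(self):
        cfg = MixingModelConfig.paper_scale()
        assert cfg.iterations > cfg.burn_in
        assert cfg.chains == 3


class TestLogPosterior:
    def _one_obs_model(self, sd_extra=13.0):
        data = pd.DataFrame(
            {
                "lake_id": ["L1"],
                "taxon": ["t"],
                "d2h_corrected": [-120.0],
                "d2h_corrected_sd": [sd_extra],
                "terrestrial_mean": [-70.0],
                "terrestrial_sd": [11.2],
                "aquatic_mean": [-170.0],
                "aquatic_sd": [23.6],
            }
        )
        m = AllochthonyMixingModel(MixingModelConfig(**REDUCED))
        m._prepare(data)
        return m

    def test_matches_closed_form_normal(self):
        m = self._one_obs_model()
        phi = 0.3
        p = ilr_inverse(phi)
        mean = (1 - p) * -70.0 + p * -170.0
        var = 1.0 * ((1 - p) ** 2 * 11.2**2 + p**2 * 23.6**2) + 13.0**2
        # prior enters as the unnormalised kernel -0.5 (phi / prior_sd)^2
        expected = stats.norm.logpdf(-120.0, mean, np.sqrt(var)) - 0.5 * (phi / 10.0) ** 2
        assert m.log_posterior(np.array([phi])) == pytest.approx(expected, abs=1e-10)

    def test_negligible_source_sds_leave_extra_variance(self):
        data = pd.DataFrame(
            {
                "lake_id": ["L1"],
                "taxon": ["t"],
                "d2h_corrected": [-120.0],
                "d2h_corrected_sd": [13.0],
                "terrestrial_mean": [-70.0],
                "terrestrial_sd": [1e-9],
                "aquatic_mean": [-170.0],
                "aquatic_sd": [1e-9],
            }
        )
        m = AllochthonyMixingModel(MixingModelConfig(**REDUCED))
        m._prepare(data)
        phi = 0.0
        p = 0.5
        mean = -120.0
        expected = stats.norm.logpdf(-120.0, mean, 13.0) - 0.5 * (phi / 10.0) ** 2
        assert m.log_posterior(np.array([phi])) == pytest.approx(expected, abs=1e-8)

    def test_translation_invariance_in_delta_space(self):
        rng = np.random.default_rng(0)
        y = rng.normal(-120, 15, 10)
        base = pd.DataFrame(
            {
                "lake_id": "L1",
                "taxon": "t",
                "d2h_corrected": y,
                "d2h_corrected_sd": 13.0,
                "terrestrial_mean": -70.0,
                "terrestrial_sd": 11.2,
                "aquatic_mean": -170.0,
                "aquatic_sd": 23.6,
            }
        )
        shifted = base.copy()
        for c in ("d2h_corrected", "terrestrial_mean", "aquatic_mean"):
            shifted[c] = shifted[c] + 40.0
        m1 = AllochthonyMixingModel(MixingModelConfig(**REDUCED))
        m2 = AllochthonyMixingModel(MixingModelConfig(**REDUCED))
        m1._prepare(base)
        m2._prepare(shifted)
        grid = np.linspace(-3, 3, 21)[:, None]
        np.testing.assert_allclose(m1.log_posterior(grid), m2.log_posterior(grid), atol=1e-9)

    def test_nonfinite_input_rejected(self):
        data = pd.DataFrame(
            {
                "lake_id": ["L1"],
                "taxon": ["t"],
                "d2h_corrected": [np.nan],
                "terrestrial_mean": [-70.0],
                "terrestrial_sd": [11.2],
                "aquatic_mean": [-170.0],
                "aquatic_sd": [23.6],
            }
        )
        with pytest.raises(ValueError, match="non-finite"):
            AllochthonyMixingModel(MixingModelConfig(**REDUCED))._prepare(data)

    def test_zero_source_sd_rejected_at_fit(self):
        data = pd.DataFrame(
            {
                "lake_id": ["L1"],
                "taxon": ["t"],
                "d2h_corrected": [-120.0],
                "terrestrial_mean": [-70.0],
                "terrestrial_sd": [0.0],
                "aquatic_mean": [-170.0],
                "aquatic_sd": [23.6],
            }
        )
        with pytest.raises(ValueError, match="source SD"):
            AllochthonyMixingModel(MixingModelConfig(**REDUCED))._prepare(data)


class TestSampling:
    def test_same_seed_same_chains(self, single_cell_data):
        cfg = MixingModelConfig(chains=2, iterations=300, burn_in=150, thinning=5,
                                seed=3, **REDUCED)
        a = AllochthonyMixingModel(cfg).fit(single_cell_data)
        b = AllochthonyMixingModel(cfg).fit(single_cell_data)
        for ca, cb in zip(a.chains_, b.chains_):
            np.testing.assert_array_equal(ca, cb)

    def test_different_seed_different_chains(self, single_cell_data):
        a = AllochthonyMixingModel(
            MixingModelConfig(chains=1, iterations=300, burn_in=150, seed=1, **REDUCED)
        ).fit(single_cell_data)
        b = AllochthonyMixingModel(
            MixingModelConfig(chains=1, iterations=300, burn_in=150, seed=2, **REDUCED)
        ).fit(single_cell_data)
        assert not np.array_equal(a.chains_[0], b.chains_[0])

    def test_near_zero_allochthony_taxon_recovered(self):
        # all consumers of one taxon sit at the aquatic source mean
        taxa = (
            TaxonSpec("cladocera", "pelagic", 2.1, -0.5, 0.0),
            TaxonSpec("vendace", "pelagic", 3.0, 4.0, 0.0),  # allochthony ~ 0
        )
        cfg = GeneratorConfig(
            n_lakes=6, taxa=taxa, samples_per_taxon_lake=3, seed=3,
            residual_sd=4.0, source_sd_terrestrial=5.0, source_sd_aquatic=5.0,
            sd_lake=0.05, global_ilr_slope=0.0,
        )
        data = model_data_from(generate_dataset(cfg))
        model = AllochthonyMixingModel(
            MixingModelConfig(covariate="none", chains=2, iterations=1500,
                              burn_in=900, thinning=5, seed=3)
        ).fit(data)
        ti = model.summarize_allochthony()["taxon_intercepts"].set_index("taxon")
        assert ti.at["vendace", "allochthony_median"] < 0.05

    def test_single_chain_rhat_unavailable(self, single_cell_data):
        m = AllochthonyMixingModel(
            MixingModelConfig(chains=1, iterations=300, burn_in=150, seed=0, **REDUCED)
        ).fit(single_cell_data)
        assert np.isnan(m.rhat_max_)


class TestDiagnostics:
    @staticmethod
    def _bare_model():
        m = AllochthonyMixingModel(MixingModelConfig(**REDUCED))
        m.param_names_ = ["theta"]
        return m

    def test_identical_constant_chains_rhat_one(self):
        m = self._bare_model()
        chains = [np.full((200, 1), 2.5), np.full((200, 1), 2.5)]
        m._diagnose(chains)
        assert m.diagnostics_["rhat"].iloc[0] == 1.0
        assert m.converged_

    def test_same_distribution_chains_rhat_near_one(self):
        rng = np.random.default_rng(1)
        m = self._bare_model()
        chains = [rng.standard_normal((5000, 1)) for _ in range(3)]
        m._diagnose(chains)
        assert m.diagnostics_["rhat"].iloc[0] < 1.01

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        m = self._bare_model()
        chains = [rng.normal(0, 1, (2000, 1)), rng.normal(50, 1, (2000, 1))]
        m._diagnose(chains)
        assert m.diagnostics_["rhat"].iloc[0] > 1.1
        assert not m.converged_


class TestSummaries:
    def test_degenerate_posterior_zero_width_interval(self, single_cell_data):
        m = AllochthonyMixingModel(
            MixingModelConfig(chains=2, iterations=300, burn_in=150, seed=0, **REDUCED)
        ).fit(single_cell_data)
        m.draws_ = np.full_like(m.draws_, 0.7)
        s = m.summarize_allochthony()["taxon_intercepts"].iloc[0]
        expected = 1 - ilr_inverse(0.7)
        assert s["allochthony_median"] == pytest.approx(expected)
        assert s["allochthony_lo95"] == pytest.approx(expected)
        assert s["allochthony_hi95"] == pytest.approx(expected)

    def test_symmetric_draws_give_half(self, single_cell_data):
        m = AllochthonyMixingModel(
            MixingModelConfig(chains=2, iterations=300, burn_in=150, seed=0, **REDUCED)
        ).fit(single_cell_data)
        sym = np.linspace(-2, 2, m.draws_.shape[0])
        m.draws_ = sym[:, None].copy()
        s = m.summarize_allochthony()["taxon_intercepts"].iloc[0]
        assert s["allochthony_median"] == pytest.approx(0.5, abs=1e-9)

    def test_summary_invariants(self):
        model, _ = _fit_small()
        summary = model.summarize_allochthony()
        ti = summary["taxon_intercepts"]
        assert ((ti["allochthony_lo95"] <= ti["allochthony_median"])
                & (ti["allochthony_median"] <= ti["allochthony_hi95"])).all()
        curves = summary["curves"]
        assert ((curves["median"] >= 0) & (curves["median"] <= 1)).all()
        assert ((curves["lo95"] <= curves["median"]) & (curves["median"] <= curves["hi95"])).all()
        assert len(summary["global_curve"]) > 0
        assert len(summary["lake_taxon"]) > 0

    def test_empty_grid_rejected(self):
        model, _ = _fit_small()
        with pytest.raises(ValueError, match="grid"):
            model.summarize_allochthony(covariate_grid=[])


class TestModelComparison:
    def test_point_mass_posterior_has_zero_complexity(self, single_cell_data):
        m = AllochthonyMixingModel(
            MixingModelConfig(chains=2, iterations=300, burn_in=150, seed=0, **REDUCED)
        ).fit(single_cell_data)
        m.draws_ = np.full((500, 1), 0.4)
        m._model_fit_stats()
        assert m.p_d_ == pytest.approx(0.0, abs=1e-8)
        d_hat = -2 * m.pointwise_loglik(np.array([[0.4]])).sum()
        assert m.dic_ == pytest.approx(d_hat, abs=1e-8)

    def test_identical_fits_share_weight(self, single_cell_data):
        cfg = MixingModelConfig(chains=2, iterations=300, burn_in=150, seed=5, **REDUCED)
        a = AllochthonyMixingModel(cfg).fit(single_cell_data)
        b = AllochthonyMixingModel(cfg).fit(single_cell_data)
        table = compare_models([a, b], ["a", "b"])
        np.testing.assert_allclose(table["akaike_weight"], [0.5, 0.5])

    def test_different_data_rejected(self, single_cell_data):
        cfg = MixingModelConfig(chains=2, iterations=300, burn_in=150, seed=5, **REDUCED)
        a = AllochthonyMixingModel(cfg).fit(single_cell_data)
        other = single_cell_data.copy()
        other["d2h_corrected"] = other["d2h_corrected"] + 5.0
        b = AllochthonyMixingModel(cfg).fit(other)
        with pytest.raises(ValueError, match="different data"):
            compare_models([a, b])

    def test_requires_at_least_two_fits(self, single_cell_data):
        cfg = MixingModelConfig(chains=2, iterations=300, burn_in=150, seed=5, **REDUCED)
        a = AllochthonyMixingModel(cfg).fit(single_cell_data)
        with pytest.raises(ValueError):
            compare_models([a])
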