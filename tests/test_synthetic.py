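import numpy as np
import pytest
from scipy import stats

from poolfish import synthetic
from poolfish.engine import ModelArrays, latent_state
from poolfish.likelihood import FAMILIES, marginal_loglik_unit
from poolfish.synthetic import (DesignSpec, default_hyperparameters,
                                draw_parameters, make_design, simulate,
                                simulate_survey)


class TestMakeDesign:
    def test_fitzroy_like_dimensions(self):
        spec, ds = make_design("fitzroy_like", seed=0)
        assert ds.n_pools == 59
        assert (ds.pools["mesohabitat"] == 0).sum() == 20
        assert (ds.pools["mesohabitat"] == 1).sum() == 39
        assert ds.n_visits == 107
        spv = ds.samples_per_visit()
        assert spv.min() >= 2 and spv.max() <= 18
        mc = ds.pools["mesohabitat"] == 0
        assert ds.pools.loc[mc, "max_depth"].between(0.35, 4.8).all()
        assert ds.pools.loc[~mc, "max_depth"].between(0.1, 3.5).all()

    def test_boat_ef_only_in_deep_water(self):
        _, ds = make_design("fitzroy_like", seed=4)
        boat = ds.samples[ds.samples["gear"] == "boat_EF"]
        assert len(boat) > 0 and (boat["sample_depth"] > 1.0).all()

    def test_tiny_deterministic(self):
        _, a = make_design("tiny", seed=9)
        _, b = make_design("tiny", seed=9)
        assert a.n_pools == 3
        assert a.pools.equals(b.pools) and a.samples.equals(b.samples)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            make_design("nope", seed=0)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            DesignSpec(samples_range=(0, 5))


class TestDrawParameters:
    def test_sigma_zero_collapses_to_mean(self):
        eta1, eta2, _ = default_hyperparameters()
        L = np.linspace(-1, 1, 5)
        t = draw_parameters((eta1, eta2, np.zeros(32)), L, n_pools=3,
                            n_years=1, seed=0, sigma_pool=0.0, sigma_time=0.0)
        for fam in ("beta1", "phi1_boat_EF"):
            i = FAMILIES.index(fam)
            assert np.allclose(t.params.coeff(fam), eta1[i] + eta2[i] * L)
        assert not t.params.eps_pool.any()

    def test_seed_determinism(self):
        L = np.linspace(-1, 1, 4)
        a = draw_parameters(length_std=L, n_pools=2, n_years=1, seed=7)
        b = draw_parameters(length_std=L, n_pools=2, n_years=1, seed=7)
        assert np.array_equal(a.params.beta, b.params.beta)

    def test_sampling_distribution(self):
        """Mean of many β1 draws matches η1 + η2·L (CLT check)."""
        eta1, eta2, sigma = default_hyperparameters()
        L = np.array([-1.0, 1.0])
        draws = np.array([
            draw_parameters(length_std=L, n_pools=1, n_years=1,
                            seed=s).params.beta[:, 0]
            for s in range(4000)])
        mu = eta1[0] + eta2[0] * L
        se = sigma[0] / np.sqrt(4000)
        assert np.all(np.abs(draws.mean(axis=0) - mu) < 3.5 * se)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            draw_parameters((np.zeros(32), np.zeros(32), -np.ones(32)),
                            np.zeros(2), seed=0)


class TestSimulateSurvey:
    def test_zero_lambda_gives_no_detections(self):
        _, ds = make_design("tiny", seed=2)
        eta1, eta2, sigma = default_hyperparameters()
        eta1 = eta1.copy()
        eta1[0] = -40.0              # λ ≈ 0 everywhere
        t = draw_parameters((eta1, eta2, np.zeros(32)),
                            ds.species["length_std"].to_numpy(),
                            n_pools=3, n_years=1, seed=0,
                            sigma_pool=0.0, sigma_time=0.0)
        sim = simulate_survey(ds, t, seed=0)
        assert sim.detections.y.sum() == 0

    def test_detection_frequency_matches_marginal(self):
        """Empirical detection rates agree with the truncated-sum marginal."""
        sim = simulate("tiny", seed=5)
        arrays = ModelArrays.from_dataset(sim)
        loglam, r = latent_state(sim.truth.params, arrays)
        n_rep = 600
        hits = np.zeros((arrays.n_species, arrays.n_samples))
        for rep in range(n_rep):
            rep_ds = simulate_survey(sim, sim.truth, seed=1000 + rep)
            hits += ModelArrays.from_dataset(rep_ds).y
        freq = hits / n_rep
        lam = np.exp(loglam)
        marg = -np.expm1(lam[:, arrays.visit_of] * (np.exp(np.log1p(
            -np.minimum(r, 1 - 1e-12))) - 1.0))      # 1 − e^{−λr}
        se = np.sqrt(np.maximum(marg * (1 - marg), 1e-8) / n_rep)
        assert np.all(np.abs(freq - marg) < 4 * se + 1e-2)

    def test_truth_bundle_attached_and_consistent(self, small_dataset):
        t = small_dataset.truth
        assert t.lam.shape == (small_dataset.n_species, small_dataset.n_visits)
        assert (t.N >= 0).all()
        assert ((t.r >= 0) & (t.r <= 1)).all()
        # detections only where the latent population is present
        arrays = ModelArrays.from_dataset(small_dataset)
        present = t.N[:, arrays.visit_of] > 0
        assert not np.any(arrays.y[~present])

    def test_lambda_monotone_below_peak(self):
        """For a species with D* ≥ 1 mean abundance rises with pool depth."""
        _, ds = make_design("fitzroy_small", seed=6)
        eta1, eta2, sigma = default_hyperparameters()
        eta1, eta2 = eta1.copy(), eta2.copy()
        eta1[1] = -0.5               # β2 < 0 => D* = e^{0.5} > 1
        eta2[1] = 0.0
        eta1[4:10] = eta2[4:10] = 0.0   # isolate the depth response
        t = draw_parameters((eta1, eta2, np.zeros(32)),
                            ds.species["length_std"].to_numpy(),
                            n_pools=ds.n_pools, n_years=1, seed=0,
                            sigma_pool=0.0, sigma_time=0.0)
        sim = simulate_survey(ds, t, seed=0)
        arrays = ModelArrays.from_dataset(sim)
        mc = arrays.M == 0
        order = np.argsort(arrays.D[mc])
        lam = sim.truth.lam[:, mc][:, order]
        assert np.all(np.diff(lam, axis=1) > -1e-12)
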