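import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolfish.data import GEARS, ScalingInfo
from poolfish.likelihood import ModelParameters, N_PHI
from poolfish.scenarios import (ScenarioSpec, apply_min_depth_rule,
                                apply_percent_reduction, distribution_loss,
                                expected_occupied_pools, objective_curve,
                                pool_log_lambda)


def point_params(n_species, n_pools, beta=None):
    """A posterior collapsed to known values, no random effects."""
    b = np.zeros((n_species, 10))
    if beta is not None:
        b[:, :beta.shape[1]] = beta
    return ModelParameters(
        beta=b, phi={g: np.zeros((n_species, N_PHI[g])) for g in GEARS},
        upsilon={g: 0.5 for g in GEARS}, sigma_lm=1.0,
        eps_pool=np.zeros(n_pools), eps_time=np.zeros(1),
        sigma_pool=0.5, sigma_time=0.3, eta1=np.zeros(32),
        eta2=np.zeros(32), sigma=np.full(32, 0.3))


def toy_pools(depths, meso=0):
    n = len(depths)
    return pd.DataFrame({
        "pool_id": [f"P{i}" for i in range(n)],
        "mesohabitat": meso, "max_depth": depths,
        "turbidity_std": 0.0, "complexity_std": 0.0, "river_km_std": 0.0,
    })


def toy_scaling(depth_divisor):
    return ScalingInfo(depth_divisor=depth_divisor, sample_depth_divisor=1.0,
                       effort_divisor={g: 1.0 for g in GEARS},
                       center={"turbidity": 0.0}, sd={"turbidity": 1.0})


class TestDepthRules:
    def test_min_depth_reference(self):
        assert np.allclose(apply_min_depth_rule([2.0, 1.0], 1.65), [1.65, 1.0])
        d = np.array([0.5, 2.3, 4.8])
        assert np.allclose(apply_min_depth_rule(d, 5.0), d)
        assert np.allclose(apply_min_depth_rule(d, 0.0), 0.0)
        with pytest.raises(ValueError):
            apply_min_depth_rule(d, -0.1)

    def test_percent_reduction_reference(self):
        d = np.array([1.0, 3.5])
        assert np.allclose(apply_percent_reduction(d, 0.14), 0.86 * d)
        assert np.allclose(apply_percent_reduction(d, 0.0), d)
        assert np.allclose(apply_percent_reduction(d, 0.9), 0.1 * d)
        with pytest.raises(ValueError):
            apply_percent_reduction(d, 1.2)

    @given(rules=st.lists(st.floats(0, 5), min_size=2, max_size=6),
           depths=st.lists(st.floats(0.1, 5), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_min_depth_rule_monotone(self, rules, depths):
        depths = np.asarray(depths)
        rules = sorted(rules)
        prev = apply_min_depth_rule(depths, rules[0])
        for rule in rules[1:]:
            cur = apply_min_depth_rule(depths, rule)
            assert np.all(cur >= prev - 1e-12)
            prev = cur


class TestExpectedOccupancy:
    def test_closed_forms(self):
        params = point_params(1, 2)
        pools = toy_pools([1.0, 1.0])
        scaling = toy_scaling(1.0)
        # β1 = 1 at D = 1 gives log λ = 1 − e⁰ = 0, λ = 1 per pool
        params.beta[:, 0] = 1.0
        occ = expected_occupied_pools(params, pools, scaling)
        assert occ[0] == pytest.approx(2 * (1 - np.exp(-1)), abs=1e-12)
        # λ -> 0: zero pools; λ -> inf: all pools
        params.beta[:, 0] = -200.0
        assert expected_occupied_pools(params, pools, scaling)[0] == pytest.approx(0.0)
        params.beta[:, 0] = 200.0
        assert expected_occupied_pools(params, pools, scaling)[0] == pytest.approx(2.0)

    def test_zero_depth_is_unoccupied(self):
        params = point_params(1, 2)
        occ = expected_occupied_pools(params, toy_pools([2.0, 1.0]),
                                      toy_scaling(2.0), depths_m=[0.0, 1.0])
        lam = np.exp(pool_log_lambda(params, toy_pools([2.0, 1.0]),
                                     toy_scaling(2.0), np.array([0.0, 1.0]),
                                     np.zeros(2)))
        assert lam[0, 0] == 0.0
        assert occ[0] == pytest.approx(-np.expm1(-lam[0, 1]))

    def test_additive_over_pool_subsets(self):
        params = point_params(2, 4)
        pools = toy_pools([0.5, 1.0, 2.0, 4.0])
        scaling = toy_scaling(4.0)
        full = expected_occupied_pools(params, pools, scaling)
        part = (expected_occupied_pools(params, pools.iloc[:2], scaling)
                + expected_occupied_pools(params, pools.iloc[2:], scaling))
        assert np.allclose(full, part)


class TestDistributionLoss:
    def test_reference_values(self):
        assert distribution_loss([10.0], [9.0])[0] == pytest.approx(10.0)
        assert distribution_loss([3.0], [3.0])[0] == pytest.approx(0.0)
        # gains are negative and must not be clipped
        assert distribution_loss([2.0], [2.2])[0] == pytest.approx(-10.0)

    def test_zero_baseline_flagged(self):
        with pytest.warns(UserWarning, match="zero baseline"):
            out = distribution_loss([0.0, 5.0], [0.0, 4.0])
        assert np.isnan(out[0]) and out[1] == pytest.approx(20.0)


class TestObjectiveCurve:
    def make_case(self):
        """5 main-channel pools, single species with a known Ricker response."""
        import poolfish.data as pfd
        from poolfish.data import DetectionArray, SurveyDataset

        depths = np.array([0.6, 1.0, 1.8, 3.0, 4.0])
        pools = toy_pools(depths).assign(
            turbidity=10.0, complexity=20.0, river_km=5.0, conductivity=300.0)
        species = pd.DataFrame({"species_id": ["S1"], "mean_length": [100.0],
                                "length_std": [0.0]})
        visits = pd.DataFrame({"visit_id": ["V0"], "pool_id": ["P0"],
                               "year": [2018]})
        samples = pd.DataFrame({
            "sample_id": ["K0"], "visit_id": ["V0"], "gear": ["seine_SM"],
            "effort_raw": [10.0], "sample_depth": [0.5],
            "sample_complexity": [20.0], "seine_variant": ["none"],
            "sample_depth_scaled": [0.5], "sample_complexity_std": [0.0],
            "effort_scaled": [1.0]})
        pools = pools.assign(depth_scaled=depths / 4.0)
        ds = SurveyDataset(
            species=species, pools=pools, visits=visits, samples=samples,
            detections=DetectionArray(y=np.zeros((1, 1, 1), np.int8),
                                      mask=np.ones((1, 1), bool)),
            scaling=toy_scaling(4.0))
        params = point_params(1, 5, beta=np.array([[1.2, 0.4]]))
        return ds, params, depths

    def test_matches_hand_computation(self):
        ds, params, depths = self.make_case()
        spec = ScenarioSpec(kind="min_depth", grid=np.array([0.5, 1.0, 2.0]),
                            mesohabitat=0)
        res = objective_curve(params, ds, spec)

        def occupied(d_raw):
            D = d_raw / 4.0
            with np.errstate(divide="ignore"):
                loglam = 1.2 + np.log(D) - np.exp(0.4) * D
            lam = np.where(D > 0, np.exp(loglam), 0.0)
            return (1 - np.exp(-lam)).sum()

        base = occupied(depths)
        for ri, rule in enumerate(spec.grid):
            want = 100 * (base - occupied(np.minimum(depths, rule))) / base
            assert res.loss_mean[0, ri] == pytest.approx(want, abs=1e-10)

    def test_no_extraction_endpoint_zero_loss(self):
        ds, params, depths = self.make_case()
        spec = ScenarioSpec(kind="min_depth",
                            grid=np.array([1.0, depths.max() + 1.0]))
        res = objective_curve(params, ds, spec)
        assert res.loss_mean[0, -1] == 0.0
        counts = res.objective_counts()
        last = counts[counts["rule"] == spec.grid[-1]]
        assert (last["n_species"] == 1).all()

    def test_percent_reduction_loss_increases_for_deep_optimum(self):
        ds, params, depths = self.make_case()
        # pools are main channel here; target them explicitly
        params.beta[:, 1] = -1.5      # D* = e^{1.5} ≈ 4.5 > max depth
        spec = ScenarioSpec(kind="percent_reduction", mesohabitat=0,
                            grid=np.round(np.arange(0.0, 0.81, 0.1), 10))
        res = objective_curve(params, ds, spec)
        losses = res.loss_mean[0]
        assert losses[0] == 0.0
        assert np.all(np.diff(losses) > 0)

    def test_most_liberal_rule_orientation(self):
        ds, params, depths = self.make_case()
        spec = ScenarioSpec(kind="min_depth", grid=np.array([0.5, 1.0, 2.0]),
                            objectives=(5.0,))
        res = objective_curve(params, ds, spec)
        tab = res.most_liberal_rule()
        ok = res.loss_mean[0] < 5.0
        expect = spec.grid[ok.argmax()] if ok.any() else np.nan
        assert tab["rule"].iloc[0] == pytest.approx(expect, nan_ok=True)

    def test_empty_target_mesohabitat_rejected(self):
        ds, params, _ = self.make_case()
        spec = ScenarioSpec(kind="percent_reduction")   # targets floodplain
        with pytest.raises(ValueError, match="mesohabitat"):
            objective_curve(params, ds, spec)


def test_scenario_spec_defaults():
    s1 = ScenarioSpec(kind="min_depth")
    assert s1.mesohabitat == 0
    assert s1.grid[0] == pytest.approx(0.5) and s1.grid[-1] == pytest.approx(2.0)
    assert len(s1.grid) == 31
    s2 = ScenarioSpec(kind="percent_reduction")
    assert s2.mesohabitat == 1
    assert len(s2.grid) == 46 and s2.grid[-1] == pytest.approx(0.9)
    assert s1.objectives == (5.0, 10.0, 15.0)
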