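"""Generative simulator for multi-gear pool surveys.

Surveys are drawn from the exact model the package fits, at designs that
emulate a dry-season field campaign on a tropical intermittent river: a
few tens of main-channel and floodplain pools spanning wide depth ranges,
each pool visited in one or more years, 2–18 spatially distinct gear
samples per visit across boat/backpack electrofishing and two seine types,
with boat electrofishing restricted to water deeper than 1 m.

The default truth hyperparameters encode the qualitative community
structure expected in such systems — smaller species more abundant
overall but peaking in shallower pools, larger species peaking deeper,
negative turbidity effects on abundance, and gear mean catchabilities
around 0.03 (backpack EF), 0.06 (boat EF), 0.21 (large-mesh seine) and
0.15 (small-mesh seine).  They are simulator presets, not estimates.
Covariate distributions (log-normal turbidity and conductivity, uniform
complexity and river km) are likewise stand-ins chosen for realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (GEARS, DetectionArray, SurveyDataset, build_detection_array,
                   scale_covariates)
from .likelihood import FAMILIES, N_PHI, ModelParameters

PRESETS = ("fitzroy_like", "fitzroy_small", "tiny")


@dataclass
class DesignSpec:
    """Survey design: sizes, allocation rules and covariate distributions."""

    n_species: int = 21
    n_pools_mc: int = 20
    n_pools_fp: int = 39
    n_years: int = 4
    n_visits: int = 107                 # total site-visits (pool × year)
    samples_range: tuple[int, int] = (2, 18)
    depth_range_mc: tuple[float, float] = (0.35, 4.8)   # m
    depth_range_fp: tuple[float, float] = (0.1, 3.5)    # m
    boat_min_depth: float = 1.0          # m; hard allocation rule
    backpack_max_depth: float = 1.2      # m; backpack EF kept shallow
    turbidity_logmean: float = np.log(8.0)    # NTU, log-normal
    turbidity_logsd: float = 1.0
    complexity_range: tuple[float, float] = (0.0, 80.0)  # percent cover
    river_km_range: tuple[float, float] = (0.0, 300.0)
    conductivity_logmean: float = np.log(300.0)  # µS/cm, log-normal
    conductivity_logsd: float = 0.7
    effort_ef: tuple[float, float] = (100.0, 1200.0)   # seconds
    effort_seine: tuple[float, float] = (5.0, 60.0)    # metres hauled
    lm10_prob: float = 0.7               # 10-m large-mesh variant share
    length_logmean: float = np.log(80.0)  # mm, log-normal species lengths
    length_logsd: float = 0.8

    def __post_init__(self) -> None:
        if self.samples_range[0] < 1:
            raise ValueError("samples per visit must be >= 1")
        for lo, hi in (self.samples_range, self.depth_range_mc,
                       self.depth_range_fp, self.complexity_range,
                       self.river_km_range, self.effort_ef, self.effort_seine):
            if not lo <= hi:
                raise ValueError("invalid range in design spec")
        if self.n_visits < self.n_pools_mc + self.n_pools_fp:
            raise ValueError("need at least one visit per pool")
        if self.n_visits > (self.n_pools_mc + self.n_pools_fp) * self.n_years:
            raise ValueError("more visits than distinct (pool, year) pairs")


_PRESET_SPECS = {
    "fitzroy_like": dict(),
    "fitzroy_small": dict(n_species=12, n_pools_mc=10, n_pools_fp=20,
                          n_years=1, n_visits=30, samples_range=(6, 6)),
    "tiny": dict(n_species=2, n_pools_mc=1, n_pools_fp=2, n_years=1,
                 n_visits=3, samples_range=(2, 2)),
}


#: default truth hyperparameters per family: (eta1, eta2, sigma)
DEFAULT_HYPER = {
    "beta1": (3.0, -0.5, 0.3), "beta2": (0.3, -0.6, 0.3),
    "beta3": (-0.7, -0.3, 0.3), "beta4": (0.2, 0.4, 0.3),
    "beta5": (-0.5, -0.2, 0.3), "beta6": (-0.2, 0.0, 0.3),
    "beta7": (0.15, -0.15, 0.2), "beta8": (-0.15, 0.1, 0.2),
    "beta9": (0.0, 0.0, 0.3), "beta10": (0.0, 0.0, 0.2),
    "phi1_backpack_EF": (-2.3, -0.3, 0.3), "phi2_backpack_EF": (0.3, -0.5, 0.3),
    "phi3_backpack_EF": (0.3, 0.0, 0.3), "phi4_backpack_EF": (-0.15, -0.1, 0.2),
    "phi5_backpack_EF": (0.1, 0.1, 0.2), "phi6_backpack_EF": (0.2, 0.0, 0.3),
    "phi1_boat_EF": (-1.6, 0.3, 0.3), "phi2_boat_EF": (0.3, -0.5, 0.3),
    "phi3_boat_EF": (0.3, 0.0, 0.3), "phi4_boat_EF": (-0.15, -0.1, 0.2),
    "phi5_boat_EF": (0.1, 0.0, 0.2), "phi6_boat_EF": (0.2, 0.0, 0.3),
    "phi1_seine_LM": (-0.4, 0.2, 0.4), "phi2_seine_LM": (0.3, -0.5, 0.3),
    "phi3_seine_LM": (0.3, 0.0, 0.3), "phi4_seine_LM": (-0.3, -0.1, 0.2),
    "phi5_seine_LM": (-0.1, 0.0, 0.2),
    "phi1_seine_SM": (-0.7, -0.3, 0.4), "phi2_seine_SM": (0.3, -0.5, 0.3),
    "phi3_seine_SM": (0.3, 0.0, 0.3), "phi4_seine_SM": (-0.15, -0.1, 0.2),
    "phi5_seine_SM": (-0.1, 0.0, 0.2),
}

DEFAULT_UPSILON = {"backpack_EF": 0.6, "boat_EF": 0.5,
                   "seine_LM": 0.7, "seine_SM": 0.4}
DEFAULT_SIGMA_LM = 0.7
DEFAULT_SIGMA_POOL = 0.5
DEFAULT_SIGMA_TIME = 0.3


def default_hyperparameters() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(eta1, eta2, sigma) arrays over the 32 families, in FAMILIES order."""
    eta1 = np.array([DEFAULT_HYPER[f][0] for f in FAMILIES])
    eta2 = np.array([DEFAULT_HYPER[f][1] for f in FAMILIES])
    sigma = np.array([DEFAULT_HYPER[f][2] for f in FAMILIES])
    return eta1, eta2, sigma


@dataclass
class TruthBundle:
    """Generating parameters, optionally with the realized latent state."""

    params: ModelParameters
    lam: np.ndarray | None = None    # (S, V) expected abundance
    N: np.ndarray | None = None      # (S, V) latent abundance
    r: np.ndarray | None = None      # (S, K) capture probability
    p: np.ndarray | None = None      # (S, K) detection probability


# ----------------------------------------------------------------------
def make_design(preset: str = "fitzroy_like", seed: int = 0,
                **overrides) -> tuple[DesignSpec, SurveyDataset]:
    """Realize a survey skeleton (no detections yet) for a named preset.

    Returns the design spec and a scaled, validated SurveyDataset whose
    detection array is all-zero; simulate_survey fills it in.
    """
    if preset not in _PRESET_SPECS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    spec = DesignSpec(**{**_PRESET_SPECS[preset], **overrides})
    rng = np.random.default_rng(seed)

    n_pools = spec.n_pools_mc + spec.n_pools_fp
    meso = np.r_[np.zeros(spec.n_pools_mc, int), np.ones(spec.n_pools_fp, int)]
    lo = np.where(meso == 0, spec.depth_range_mc[0], spec.depth_range_fp[0])
    hi = np.where(meso == 0, spec.depth_range_mc[1], spec.depth_range_fp[1])
    pools = pd.DataFrame({
        "pool_id": [f"P{j:03d}" for j in range(n_pools)],
        "mesohabitat": meso,
        "max_depth": rng.uniform(lo, hi),
        "turbidity": rng.lognormal(spec.turbidity_logmean, spec.turbidity_logsd, n_pools),
        "complexity": rng.uniform(*spec.complexity_range, n_pools),
        "river_km": rng.uniform(*spec.river_km_range, n_pools),
        "conductivity": rng.lognormal(spec.conductivity_logmean,
                                      spec.conductivity_logsd, n_pools),
    })

    # every pool visited at least once; extra (pool, year) pairs drawn
    # without replacement up to the target visit count
    years = 2018 + np.arange(spec.n_years)
    first = rng.integers(0, spec.n_years, n_pools)
    pairs = {(j, int(first[j])) for j in range(n_pools)}
    remaining = [(j, t) for j in range(n_pools) for t in range(spec.n_years)
                 if (j, t) not in pairs]
    extra = spec.n_visits - n_pools
    if extra:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        pairs |= {remaining[i] for i in idx}
    pairs = sorted(pairs)
    visits = pd.DataFrame({
        "visit_id": [f"V{n:03d}" for n in range(len(pairs))],
        "pool_id": [pools["pool_id"][j] for j, _ in pairs],
        "year": [int(years[t]) for _, t in pairs],
    })

    rows = []
    for v, (j, _) in zip(visits["visit_id"], pairs):
        depth = float(pools["max_depth"][j])
        n_samp = int(rng.integers(spec.samples_range[0], spec.samples_range[1] + 1))
        for k in range(n_samp):
            d = float(rng.uniform(0.3, 1.0) * depth)
            candidates = ["seine_LM", "seine_SM"]
            if d > spec.boat_min_depth:
                candidates.append("boat_EF")
            if d <= spec.backpack_max_depth:
                candidates.append("backpack_EF")
            gear = candidates[rng.integers(len(candidates))]
            if gear in ("backpack_EF", "boat_EF"):
                effort = float(rng.uniform(*spec.effort_ef))
            else:
                effort = float(rng.uniform(*spec.effort_seine))
            variant = "none"
            if gear == "seine_LM":
                variant = "seine10m" if rng.random() < spec.lm10_prob else "seine5m"
            s_cplx = float(np.clip(pools["complexity"][j] + rng.normal(0, 10), 0, 100))
            rows.append((f"{v}_S{k:02d}", v, gear, effort, d, s_cplx, variant))
    samples = pd.DataFrame(rows, columns=["sample_id", "visit_id", "gear",
                                          "effort_raw", "sample_depth",
                                          "sample_complexity", "seine_variant"])
    samples["complexity_imputed"] = False

    species = pd.DataFrame({
        "species_id": [f"SP{i:02d}" for i in range(spec.n_species)],
        "mean_length": np.sort(rng.lognormal(spec.length_logmean,
                                             spec.length_logsd, spec.n_species)),
    })
    da = build_detection_array(samples, visits, species, pd.DataFrame(columns=[
        "species_id", "sample_id", "value"]))
    ds = SurveyDataset(species=species, pools=pools, visits=visits,
                       samples=samples, detections=da)
    return spec, scale_covariates(ds)


# ----------------------------------------------------------------------
def draw_parameters(hyper=None, length_std=None, n_pools: int = 1,
                    n_years: int = 1, seed: int = 0,
                    upsilon=None, sigma_lm: float = DEFAULT_SIGMA_LM,
                    sigma_pool: float = DEFAULT_SIGMA_POOL,
                    sigma_time: float = DEFAULT_SIGMA_TIME) -> TruthBundle:
    """Draw species coefficients and random effects from the hierarchy.

    coeff_{s,i} ~ Normal(η1_s + η2_s·L_i, σ_s²) per family; σ_s = 0 is the
    degenerate limit coeff = μ exactly.
    """
    eta1, eta2, sigma = hyper if hyper is not None else default_hyperparameters()
    eta1, eta2, sigma = (np.asarray(a, float) for a in (eta1, eta2, sigma))
    if np.any(sigma < 0) or sigma_pool < 0 or sigma_time < 0:
        raise ValueError("SD hyperparameters must be >= 0")
    if eta1.shape != (len(FAMILIES),):
        raise ValueError(f"expected {len(FAMILIES)} families")
    L = np.asarray(length_std, float)
    rng = np.random.default_rng(seed)
    mu = eta1[:, None] + eta2[:, None] * L[None, :]
    coeff = rng.normal(mu, sigma[:, None])
    beta = coeff[:10].T
    phi, off = {}, 10
    for g in GEARS:
        phi[g] = coeff[off:off + N_PHI[g]].T
        off += N_PHI[g]
    params = ModelParameters(
        beta=beta, phi=phi,
        upsilon=dict(upsilon or DEFAULT_UPSILON), sigma_lm=float(sigma_lm),
        eps_pool=rng.normal(0.0, sigma_pool, n_pools),
        eps_time=rng.normal(0.0, sigma_time, n_years),
        sigma_pool=float(sigma_pool), sigma_time=float(sigma_time),
        eta1=eta1, eta2=eta2, sigma=sigma)
    return TruthBundle(params=params)


def simulate_survey(dataset: SurveyDataset, truth: TruthBundle,
                    seed: int = 0) -> SurveyDataset:
    """Fill detections by running the generative chain.

    λ from the abundance predictor, N ~ Poisson(λ), r from the gear
    catchability sub-models, y ~ Bernoulli(1 − (1 − r)^N).
    """
    from .engine import ModelArrays, latent_state

    arrays = ModelArrays.from_dataset(dataset)
    loglam, r = latent_state(truth.params, arrays)
    lam = np.exp(loglam)
    rng = np.random.default_rng(seed)
    N = rng.poisson(lam)
    p = -np.expm1(N[:, arrays.visit_of] * np.log1p(-np.minimum(r, 1 - 1e-12)))
    y_flat = (rng.random(p.shape) < p).astype(np.int8)

    vis, slot = np.nonzero(dataset.detections.mask)
    order = np.lexsort((np.arange(arrays.n_samples), arrays.visit_of))
    y = np.zeros_like(dataset.detections.y)
    y[:, vis, slot] = y_flat[:, order]
    da = DetectionArray(y=y, mask=dataset.detections.mask)
    truth = replace(truth, lam=lam, N=N, r=r, p=p)
    return replace(dataset, detections=da, truth=truth)


def simulate(preset: str = "fitzroy_like", seed: int = 0, hyper=None,
             **design_overrides) -> SurveyDataset:
    """Convenience: design + parameter draw + survey in one seeded call."""
    ss = np.random.SeedSequence(seed).generate_state(3)
    spec, ds = make_design(preset, seed=int(ss[0] % 2**31), **design_overrides)
    truth = draw_parameters(hyper=hyper,
                            length_std=ds.species["length_std"].to_numpy(),
                            n_pools=ds.n_pools,
                            n_years=ds.visits["year"].nunique(),
                            seed=int(ss[1] % 2**31))
    return simulate_survey(ds, truth, seed=int(ss[2] % 2**31))
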