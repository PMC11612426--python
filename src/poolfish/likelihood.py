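"""The joint probability model for multi-gear pool surveys.

Latent abundance of species *i* at site-visit *j* is Poisson(λ_ij) with a
Ricker-shaped depth response on the log scale,

    log λ = (β1 + β3·M) + log D − exp(β2 + β4·M)·D
            + β5·T + β6·T·M + β7·S + β8·S·M + β9·R + β10·R·M
            + ε_pool + ε_time,

so λ → 0 as depth D → 0 and is unimodal in D with its maximum at
D* = exp(−(β2 + β4·M)).  Each gear sample has a catchability predictor

    log q = φ1 + log D́ − exp(φ2)·D́ + φ3·T + φ4·T² + φ5·Ś [+ φ6·C]

(the conductivity term only for electrofishing gears), converted to a
capture probability r = ς·E^υ·(1 − exp(−q)) where E ∈ (0,1] is scaled
effort, υ ∈ [0,1] the effort-shape exponent and ς ∈ (0,1] the short-seine
scalar (1 except for 5-m large-mesh seine hauls).  Detection of at least
one individual has probability p = 1 − (1 − r)^N, and the observation-level
likelihood marginalizes N over a truncated Poisson support.

Species-level coefficients follow the fourth-corner hierarchy: for each
coefficient family s, coeff_{s,i} ~ Normal(η1_s + η2_s·L_i, σ_s²) with L_i
the standardized species mean length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .data import EF_GEARS, GEARS

#: species-level coefficients per gear observation sub-model
N_PHI = {"backpack_EF": 6, "boat_EF": 6, "seine_LM": 5, "seine_SM": 5}

#: the 32 coefficient families of the fourth-corner hierarchy
BETA_FAMILIES = tuple(f"beta{s}" for s in range(1, 11))
PHI_FAMILIES = tuple(f"phi{s}_{g}" for g in GEARS for s in range(1, N_PHI[g] + 1))
FAMILIES = BETA_FAMILIES + PHI_FAMILIES
N_FAMILIES = len(FAMILIES)          # 32


@dataclass
class PoolCovariates:
    """Scaled pool/visit covariates entering the abundance predictor."""
    D: float          # max depth scaled to (0, 1]
    M: int = 0        # mesohabitat: 0 main channel, 1 floodplain
    T: float = 0.0    # turbidity, standardized
    S: float = 0.0    # structural complexity, standardized
    R: float = 0.0    # river km, standardized


@dataclass
class SampleCovariates:
    """Scaled sample covariates entering a gear catchability predictor."""
    D: float              # sample depth scaled to (0, 1]
    T: float = 0.0        # pool turbidity, standardized
    S: float = 0.0        # sample complexity, standardized
    C: float | None = None  # pool conductivity, standardized (EF gears only)


@dataclass
class ModelParameters:
    """All natural-scale parameters of the joint model."""

    beta: np.ndarray                    # (n_species, 10)
    phi: dict[str, np.ndarray]          # gear -> (n_species, N_PHI[gear])
    upsilon: dict[str, float]           # gear -> effort exponent in [0, 1]
    sigma_lm: float                     # ς, 5-m large-mesh seine scalar
    eps_pool: np.ndarray                # per physical pool
    eps_time: np.ndarray                # per year
    sigma_pool: float
    sigma_time: float
    eta1: np.ndarray                    # (32,) family intercepts
    eta2: np.ndarray                    # (32,) family length slopes
    sigma: np.ndarray                   # (32,) family SDs

    def coeff(self, family: str) -> np.ndarray:
        """Species-level coefficients of one family (column view)."""
        idx = FAMILIES.index(family)
        if idx < 10:
            return self.beta[:, idx]
        off = 10
        for g in GEARS:
            if idx < off + N_PHI[g]:
                return self.phi[g][:, idx - off]
            off += N_PHI[g]
        raise KeyError(family)


# ----------------------------------------------------------------------
# deterministic model pieces

def abundance_linpred(beta_i, pool: PoolCovariates,
                      eps_pool: float = 0.0, eps_time: float = 0.0) -> float:
    """log λ for one species at one visit; −inf at D = 0 (λ = 0 limit)."""
    b = np.asarray(beta_i, float)
    if b.shape[-1] != 10:
        raise ValueError("expected 10 abundance coefficients")
    if pool.D < 0:
        raise ValueError("scaled depth must be >= 0")
    if pool.D == 0:
        return -np.inf
    return float((b[0] + b[2] * pool.M) + np.log(pool.D)
                 - np.exp(b[1] + b[3] * pool.M) * pool.D
                 + b[4] * pool.T + b[5] * pool.T * pool.M
                 + b[6] * pool.S + b[7] * pool.S * pool.M
                 + b[8] * pool.R + b[9] * pool.R * pool.M
                 + eps_pool + eps_time)


def peak_depth(beta2, beta4=0.0, M=0):
    """Scaled depth D* = exp(−(β2 + β4·M)) maximizing λ over D > 0.

    Values above 1 mean abundance rises monotonically across the observed
    (scaled) depth range.
    """
    return np.exp(-(np.asarray(beta2, float) + np.asarray(beta4, float) * M))


def catchability_linpred(phi_i, sample: SampleCovariates, gear: str) -> float:
    """log q for one species in one gear sample."""
    if gear not in GEARS:
        raise ValueError(f"unknown gear {gear!r}")
    p = np.asarray(phi_i, float)
    if p.shape[-1] != N_PHI[gear]:
        raise ValueError(f"{gear} expects {N_PHI[gear]} coefficients, got {p.shape[-1]}")
    if sample.C is not None and gear not in EF_GEARS:
        raise ValueError("conductivity is only modelled for electrofishing gears")
    if sample.D <= 0:
        raise ValueError("scaled sample depth must be > 0")
    out = (p[0] + np.log(sample.D) - np.exp(p[1]) * sample.D
           + p[2] * sample.T + p[3] * sample.T ** 2 + p[4] * sample.S)
    if gear in EF_GEARS:
        if sample.C is None:
            raise ValueError("electrofishing sample requires conductivity")
        out += p[5] * sample.C
    return float(out)


def capture_prob(log_q, effort_scaled, upsilon, lm_scalar: float = 1.0):
    """r = ς·E^υ·(1 − exp(−q)) with q = exp(log q); vectorized.

    υ = 1 gives capture probability proportional to effort, υ = 0 removes
    the effort dependence entirely; ς < 1 only for 5-m large-mesh seines.
    """
    E = np.asarray(effort_scaled, float)
    if np.any(E < 0) or np.any(E > 1):
        raise ValueError("scaled effort must lie in [0, 1]")
    if not 0 <= upsilon <= 1:
        raise ValueError("effort exponent must lie in [0, 1]")
    if not 0 < lm_scalar <= 1:
        raise ValueError("seine scalar must lie in (0, 1]")
    if upsilon == 0:
        eff = np.ones_like(E)
    else:
        with np.errstate(divide="ignore"):
            eff = np.where(E > 0, E, 0.0) ** upsilon
    return lm_scalar * eff * (-np.expm1(-np.exp(np.asarray(log_q, float))))


def detection_prob(r, N):
    """p = 1 − (1 − r)^N, evaluated as −expm1(N·log1p(−r)) for stability."""
    r = np.minimum(np.asarray(r, float), 1 - 1e-12)
    if np.any(r < 0):
        raise ValueError("capture probability must be >= 0")
    N = np.asarray(N)
    return -np.expm1(N * np.log1p(-r))


# ----------------------------------------------------------------------
# marginal likelihood

def choose_n_max(lam: float, tail: float = 1e-10, floor: int = 50,
                 cap: int = 5000) -> int:
    """Smallest Poisson support bound with tail mass below ``tail``."""
    n = int(stats.poisson.ppf(1.0 - tail, max(float(lam), 1e-12)))
    return int(min(max(n, floor), cap))


def marginal_loglik_unit(lam: float, r, y, n_max: int | None = None) -> float:
    """Log-likelihood of one (species, visit) detection history.

    Marginalizes the latent abundance N over 0..n_max:
        log Σ_N Poisson(N | λ) Π_k p_k(N)^{y_k} (1 − p_k(N))^{1−y_k}
    with p_k(N) = 1 − (1 − r_k)^N, log-sum-exp stabilized.
    """
    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    r = np.atleast_1d(np.asarray(r, float))
    y = np.atleast_1d(np.asarray(y, int))
    if r.shape != y.shape:
        raise ValueError("r and y must align")
    if lam == 0:
        return 0.0 if not y.any() else -np.inf
    if n_max is None:
        n_max = choose_n_max(lam)
    N = np.arange(n_max + 1)
    rc = np.minimum(r, 1 - 1e-12)
    l1p = np.log1p(-rc)                                     # log(1 − r_k)
    # log Poisson pmf over the support
    a = N * np.log(lam) - lam - gammaln(N + 1.0)
    # non-detections contribute N·Σ log(1 − r_k); detections log p_k(N)
    a = a + N * float(l1p[y == 0].sum())
    for lk in l1p[y == 1]:
        with np.errstate(divide="ignore"):
            a = a + np.log(-np.expm1(N * lk))
    return float(logsumexp(a))


# ----------------------------------------------------------------------
# fourth-corner hierarchy

def fourth_corner_logprior(coeffs, eta1, eta2, sigma, length_std) -> float:
    """Σ_i log Normal(coeff_i | η1 + η2·L_i, σ²) for one coefficient family."""
    if not sigma > 0:
        raise ValueError("family SD must be > 0")
    c = np.asarray(coeffs, float)
    mu = eta1 + eta2 * np.asarray(length_std, float)
    return float(stats.norm.logpdf(c, mu, sigma).sum())


def joint_log_posterior(params: ModelParameters, dataset, priors=None) -> float:
    """Unnormalized log posterior on the natural parameter scale.

    Sum of the marginalized detection likelihood over species × visits,
    the fourth-corner normal layer for every coefficient family, the
    random-effect densities, and the hyperpriors.  Returns −inf for any
    non-finite parameter value.
    """
    from .engine import ModelArrays, natural_log_posterior
    from .inference import PriorConfig

    vals = [params.beta, params.eta1, params.eta2, params.sigma,
            params.eps_pool, params.eps_time,
            [params.sigma_pool, params.sigma_time, params.sigma_lm],
            list(params.upsilon.values())] + [params.phi[g] for g in GEARS]
    if not all(np.all(np.isfinite(np.asarray(v, float))) for v in vals):
        return -np.inf
    priors = priors if priors is not None else PriorConfig()
    arrays = dataset if isinstance(dataset, ModelArrays) else ModelArrays.from_dataset(dataset)
    return natural_log_posterior(params, arrays, priors)
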