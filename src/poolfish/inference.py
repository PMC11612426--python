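"""Priors, posterior sampling and convergence diagnostics.

The fitting protocol mirrors common hierarchical-occupancy practice: four
MCMC chains run until split R-hat is below 1.1 and the effective sample
size of every hyperparameter exceeds 400.  Regularization enters through
mildly informative priors: the half-Normal(0.5) prior on each family SD
shrinks species coefficients toward the component explained by species
length (the fourth-corner penalty).

Three samplers are provided.  The default ("nuts") is a blocked scheme on
the marginalized posterior: No-U-Turn sampling of the species
coefficients, random effects, effort parameters and family means under a
dense curvature metric, interleaved with conjugate Gibbs updates of the
family means, slice updates of the hierarchy SDs, and ancillary
(non-centered) rescaling and translation moves that decouple weakly
identified families from their hyperparameters.  A fixed-length HMC
sampler ("hmc") and an adaptive random-walk Metropolis fallback ("rw")
operate on the full vector; the fallback must agree with the default
(checked on small models in the test suite).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .data import GEARS
from .engine import (ModelArrays, ParameterLayout, log_posterior,
                     log_posterior_and_grad)
from .likelihood import FAMILIES


@dataclass
class PriorConfig:
    """Hyperprior locations/scales; scalar values broadcast over families."""

    eta1_loc: float | np.ndarray = 0.0
    eta1_scale: float | np.ndarray = 2.0
    eta2_loc: float | np.ndarray = 0.0
    eta2_scale: float | np.ndarray = 1.0
    sigma_scale: float | np.ndarray = 0.5     # half-Normal on family SDs
    sigma_pool_scale: float = 1.0             # half-Normal on pool RE SD
    sigma_time_scale: float = 1.0             # half-Normal on year RE SD
    upsilon_bounds: tuple[float, float] = (0.0, 1.0)
    sigma_lm_bounds: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("eta1_scale", "eta2_scale", "sigma_scale",
                     "sigma_pool_scale", "sigma_time_scale"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be > 0")

    def n_free(self) -> dict[str, int]:
        """Count of hyper-level quantities the priors govern."""
        return {"family_triples": len(FAMILIES), "effort_exponents": len(GEARS),
                "seine_scalars": 1, "variance_components": 2}

    def logpdf_hyper(self, eta1, eta2, sigma, sigma_pool=1.0, sigma_time=1.0) -> float:
        """Hyperprior log density; −inf outside the support (e.g. σ ≤ 0)."""
        sigma = np.asarray(sigma, float)
        if np.any(sigma <= 0) or sigma_pool <= 0 or sigma_time <= 0:
            return -np.inf
        lp = stats.norm.logpdf(eta1, self.eta1_loc, self.eta1_scale).sum()
        lp += stats.norm.logpdf(eta2, self.eta2_loc, self.eta2_scale).sum()
        lp += stats.halfnorm.logpdf(sigma, scale=self.sigma_scale).sum()
        lp += stats.halfnorm.logpdf(sigma_pool, scale=self.sigma_pool_scale)
        lp += stats.halfnorm.logpdf(sigma_time, scale=self.sigma_time_scale)
        return float(lp)


def default_priors(dataset=None) -> PriorConfig:
    """Mildly informative defaults on the scaled-covariate parameter scale."""
    return PriorConfig()


@dataclass
class MCMCConfig:
    n_chains: int = 4
    n_warmup: int = 500
    n_draws: int = 500
    seed: int = 0
    sampler: str = "nuts"             # "nuts", "hmc" or "rw"
    target_accept: float = 0.8
    max_leapfrog: int = 20            # fixed-length HMC only
    max_tree_depth: int = 7           # NUTS only
    gibbs_sweeps: int = 1             # hyper/ASIS sweeps per NUTS step
    asis_every: int = 1               # run ancillary moves every k-th step
    init_jitter: float = 0.1
    rhat_threshold: float = 1.1
    ess_min: float = 400.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for split diagnostics")
        if self.sampler not in ("nuts", "hmc", "rw"):
            raise ValueError("sampler must be 'nuts', 'hmc' or 'rw'")


# ----------------------------------------------------------------------
# diagnostics

def _per_chain(draws) -> np.ndarray:
    d = np.asarray(draws, float)
    if d.ndim != 2 or d.shape[0] < 2 or d.shape[1] < 4:
        raise ValueError("diagnostics need (chains >= 2, draws >= 4)")
    return d


def rhat(draws) -> float:
    """Split-chain potential scale reduction factor (rank-normalized).

    Returns NaN for degenerate zero-variance chains rather than raising.
    """
    d = _per_chain(draws)
    if np.allclose(d.var(axis=1), 0.0) and np.allclose(d.mean(axis=1), d.mean()):
        return float("nan")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(az.rhat(az.convert_to_dataset(d))["x"])


def ess(draws) -> float:
    """Autocorrelation-based (bulk) effective sample size; NaN if degenerate."""
    d = _per_chain(draws)
    if np.allclose(d.var(axis=1), 0.0):
        return float("nan")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return float(az.ess(az.convert_to_dataset(d))["x"])


def _diagnostics_table(draws3: np.ndarray, names: list[str]) -> pd.DataFrame:
    """R-hat and ESS per parameter from (chain, draw, param) draws."""
    ds = az.convert_to_dataset({"x": draws3})
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        r = np.asarray(az.rhat(ds)["x"])
        e = np.asarray(az.ess(ds)["x"])
    return pd.DataFrame({"parameter": names, "rhat": r, "ess": e}).set_index("parameter")


# ----------------------------------------------------------------------
# samplers

def _dual_averaging_state(step0: float, target: float):
    return {"mu": np.log(10.0 * step0), "log_eps_bar": 0.0, "h_bar": 0.0,
            "t": 0, "gamma": 0.05, "t0": 10.0, "kappa": 0.75, "target": target}


def _dual_averaging_update(state, accept_prob: float) -> float:
    state["t"] += 1
    t = state["t"]
    eta = 1.0 / (t + state["t0"])
    state["h_bar"] = (1 - eta) * state["h_bar"] + eta * (state["target"] - accept_prob)
    log_eps = state["mu"] - np.sqrt(t) / state["gamma"] * state["h_bar"]
    w = t ** -state["kappa"]
    state["log_eps_bar"] = w * log_eps + (1 - w) * state["log_eps_bar"]
    return float(np.exp(log_eps))


def _hmc_chain(logp_grad, theta0: np.ndarray, cfg: MCMCConfig, rng: np.random.Generator):
    """One HMC chain; returns (draws, accept_rate, final step size)."""
    dim = len(theta0)
    theta = theta0.copy()
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite initial log-posterior")
    inv_mass = np.ones(dim)
    step = 0.1 / dim ** 0.25
    da = _dual_averaging_state(step, cfg.target_accept)
    draws = np.empty((cfg.n_draws, dim))
    warm_buf: list[np.ndarray] = []
    # mass-update points within warmup (doubling windows, Stan-like)
    w1 = max(int(0.15 * cfg.n_warmup), 10)
    w3 = max(int(0.10 * cfg.n_warmup), 10)
    mass_updates = set()
    start, width = w1, max((cfg.n_warmup - w1 - w3) // 3, 1)
    while start + width < cfg.n_warmup - w3:
        start += width
        mass_updates.add(start)
        width *= 2
    mass_updates.add(cfg.n_warmup - w3)

    n_accept = 0.0
    total = cfg.n_warmup + cfg.n_draws
    for it in range(total):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        n_leap = int(rng.integers(1, cfg.max_leapfrog + 1))
        th, gr = theta.copy(), grad.copy()
        p = p0 + 0.5 * step * gr
        lp_new = lp
        for leap in range(n_leap):
            th = th + step * inv_mass * p
            lp_new, gr = logp_grad(th)
            if not np.isfinite(lp_new):
                break
            p = p + (0.5 if leap == n_leap - 1 else 1.0) * step * gr
        if np.isfinite(lp_new):
            h0 = -lp + 0.5 * float(p0 * inv_mass @ p0)
            h1 = -lp_new + 0.5 * float(p * inv_mass @ p)
            acc = min(1.0, float(np.exp(min(h0 - h1, 0.0))))
        else:
            acc = 0.0
        if rng.random() < acc:
            theta, lp, grad = th, lp_new, gr
        if it < cfg.n_warmup:
            step = _dual_averaging_update(da, acc)
            if it >= w1:
                warm_buf.append(theta.copy())
            if (it + 1) in mass_updates and len(warm_buf) >= 10:
                var = np.var(np.asarray(warm_buf), axis=0)
                inv_mass = np.where(var > 1e-12, var, inv_mass)
                warm_buf.clear()
                da = _dual_averaging_state(step, cfg.target_accept)
            if it == cfg.n_warmup - 1:
                step = float(np.exp(da["log_eps_bar"]))
        else:
            draws[it - cfg.n_warmup] = theta
            n_accept += acc
    return draws, n_accept / max(cfg.n_draws, 1), step


class _Tree:
    """Sub-trajectory state for iterative NUTS doubling."""

    __slots__ = ("th_m", "p_m", "gr_m", "th_p", "p_p", "gr_p",
                 "th_prop", "gr_prop", "lp_prop", "logw", "sum_p",
                 "alpha", "n_alpha", "diverged")


def _leapfrog(logp_grad, th, p, gr, eps, inv_mass):
    p = p + 0.5 * eps * gr
    th = th + eps * inv_mass * p
    lp, gr = logp_grad(th)
    p = p + 0.5 * eps * gr
    return th, p, gr, lp


def _nuts_leaf(logp_grad, th, p, gr, v, eps, inv_mass, h0):
    th, p, gr, lp = _leapfrog(logp_grad, th, p, gr, v * eps, inv_mass)
    joint = lp - 0.5 * float(p * inv_mass @ p)
    t = _Tree()
    t.th_m = t.th_p = t.th_prop = th
    t.p_m = t.p_p = p
    t.gr_m = t.gr_p = t.gr_prop = gr
    t.lp_prop = lp
    t.logw = joint - h0
    t.sum_p = inv_mass * p
    t.alpha = min(1.0, float(np.exp(min(joint - h0, 0.0)))) if np.isfinite(joint) else 0.0
    t.n_alpha = 1
    t.diverged = (not np.isfinite(joint)) or (joint - h0 < -1000.0)
    return t


def _nuts_subtree(logp_grad, th, p, gr, v, depth, eps, inv_mass, h0, rng):
    if depth == 0:
        return _nuts_leaf(logp_grad, th, p, gr, v, eps, inv_mass, h0)
    left = _nuts_subtree(logp_grad, th, p, gr, v, depth - 1, eps, inv_mass, h0, rng)
    if left.diverged:
        return left
    if v == 1:
        right = _nuts_subtree(logp_grad, left.th_p, left.p_p, left.gr_p, v,
                              depth - 1, eps, inv_mass, h0, rng)
        left.th_p, left.p_p, left.gr_p = right.th_p, right.p_p, right.gr_p
    else:
        right = _nuts_subtree(logp_grad, left.th_m, left.p_m, left.gr_m, v,
                              depth - 1, eps, inv_mass, h0, rng)
        left.th_m, left.p_m, left.gr_m = right.th_m, right.p_m, right.gr_m
    left.alpha += right.alpha
    left.n_alpha += right.n_alpha
    if right.diverged:
        left.diverged = True
        return left
    total = np.logaddexp(left.logw, right.logw)
    if np.log(rng.random()) < right.logw - total:
        left.th_prop, left.gr_prop, left.lp_prop = (
            right.th_prop, right.gr_prop, right.lp_prop)
    left.logw = total
    left.sum_p = left.sum_p + right.sum_p
    dth = left.th_p - left.th_m
    if (dth @ left.p_m) < 0 or (dth @ left.p_p) < 0:
        left.diverged = True          # treat internal U-turn as stop
    return left


def _nuts_transition(logp_grad, theta, lp, grad, step, inv_mass, max_depth, rng):
    """One multinomial No-U-Turn transition; returns (θ, lp, grad, mean α)."""
    p0 = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * float(p0 * inv_mass @ p0)
    tree = _Tree()
    tree.th_m = tree.th_p = theta
    tree.p_m = tree.p_p = p0
    tree.gr_m = tree.gr_p = tree.gr_prop = grad
    tree.th_prop, tree.lp_prop = theta, lp
    tree.logw, tree.sum_p = 0.0, inv_mass * p0
    tree.alpha, tree.n_alpha, tree.diverged = 0.0, 0, False
    for depth in range(max_depth):
        v = 1 if rng.random() < 0.5 else -1
        if v == 1:
            sub = _nuts_subtree(logp_grad, tree.th_p, tree.p_p, tree.gr_p,
                                v, depth, step, inv_mass, h0, rng)
        else:
            sub = _nuts_subtree(logp_grad, tree.th_m, tree.p_m, tree.gr_m,
                                v, depth, step, inv_mass, h0, rng)
        tree.alpha += sub.alpha
        tree.n_alpha += sub.n_alpha
        if sub.diverged:
            break
        total = np.logaddexp(tree.logw, sub.logw)
        if np.log(rng.random()) < sub.logw - total:
            tree.th_prop, tree.gr_prop, tree.lp_prop = (
                sub.th_prop, sub.gr_prop, sub.lp_prop)
        tree.logw = total
        if v == 1:
            tree.th_p, tree.p_p, tree.gr_p = sub.th_p, sub.p_p, sub.gr_p
        else:
            tree.th_m, tree.p_m, tree.gr_m = sub.th_m, sub.p_m, sub.gr_m
        dth = tree.th_p - tree.th_m
        if (dth @ tree.p_m) < 0 or (dth @ tree.p_p) < 0:
            break
    return (tree.th_prop, tree.lp_prop, tree.gr_prop,
            tree.alpha / max(tree.n_alpha, 1))


def _adaptation_schedule(n_warmup: int):
    """(buffer start, mass-update iterations) for windowed warmup adaptation."""
    w1 = max(int(0.15 * n_warmup), 10)
    w3 = max(int(0.10 * n_warmup), 10)
    updates = set()
    start, width = w1, max((n_warmup - w1 - w3) // 3, 1)
    while start + width < n_warmup - w3:
        start += width
        updates.add(start)
        width *= 2
    updates.add(n_warmup - w3)
    return w1, updates


def _nuts_chain(logp_grad, theta0: np.ndarray, cfg: MCMCConfig,
                rng: np.random.Generator):
    """One full-vector No-U-Turn chain with diagonal mass adaptation."""
    theta = theta0.copy()
    lp, grad = logp_grad(theta)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite initial log-posterior")
    inv_mass = np.ones(len(theta))
    step = 0.1 / len(theta) ** 0.25
    da = _dual_averaging_state(step, cfg.target_accept)
    draws = np.empty((cfg.n_draws, len(theta)))
    warm_buf: list[np.ndarray] = []
    w1, mass_updates = _adaptation_schedule(cfg.n_warmup)
    n_accept = 0.0
    for it in range(cfg.n_warmup + cfg.n_draws):
        theta, lp, grad, acc = _nuts_transition(
            logp_grad, theta, lp, grad, step, inv_mass, cfg.max_tree_depth, rng)
        if it < cfg.n_warmup:
            step = _dual_averaging_update(da, acc)
            if it >= w1:
                warm_buf.append(theta.copy())
            if (it + 1) in mass_updates and len(warm_buf) >= 10:
                var = np.var(np.asarray(warm_buf), axis=0)
                inv_mass = np.where(var > 1e-12, var, inv_mass)
                warm_buf.clear()
                da = _dual_averaging_state(step, cfg.target_accept)
            if it == cfg.n_warmup - 1:
                step = float(np.exp(da["log_eps_bar"]))
        else:
            draws[it - cfg.n_warmup] = theta
            n_accept += acc
    return draws, n_accept / max(cfg.n_draws, 1), step


# ----------------------------------------------------------------------
# Gibbs updates for the hierarchy level

def _slice_sample(logf, x0: float, rng, w: float = 0.7, max_steps: int = 30) -> float:
    """Univariate slice sampler (stepping out, Neal 2003)."""
    f0 = logf(x0)
    y = f0 + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logf(left) <= y:
            break
        left -= w
    for _ in range(max_steps):
        if logf(right) <= y:
            break
        right += w
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return float(x1)
        if x1 < x0:
            left = x1
        else:
            right = x1
    return float(x0)


def _gibbs_hyper_sweep(theta: np.ndarray, layout, priors, length_std, rng) -> None:
    """Exact conjugate update of (η1, η2) and slice update of every SD.

    Conditional on the species coefficients c_s, the family regression
    c_{s,i} = η1_s + η2_s·L_i + σ_s·noise is a two-coefficient normal
    linear model, so (η1_s, η2_s) has a bivariate-normal full conditional;
    the SDs have log-concave one-dimensional conditionals sampled by slice.
    """
    p = layout.unpack(theta)
    c = p["c"]
    S = c.shape[1]
    L = np.asarray(length_std, float)
    e1s = np.broadcast_to(np.asarray(priors.eta1_scale, float), (32,))
    e2s = np.broadcast_to(np.asarray(priors.eta2_scale, float), (32,))
    e1l = np.broadcast_to(np.asarray(priors.eta1_loc, float), (32,))
    e2l = np.broadcast_to(np.asarray(priors.eta2_loc, float), (32,))
    ss = np.broadcast_to(np.asarray(priors.sigma_scale, float), (32,))
    sL, sL2 = float(L.sum()), float(L @ L)
    for s in range(32):
        s2 = float(np.exp(2.0 * p["lsig"][s]))
        # (η1, η2) | c, σ — bivariate normal
        p11 = 1.0 / e1s[s] ** 2 + S / s2
        p22 = 1.0 / e2s[s] ** 2 + sL2 / s2
        p12 = sL / s2
        b1 = e1l[s] / e1s[s] ** 2 + float(c[s].sum()) / s2
        b2 = e2l[s] / e2s[s] ** 2 + float(c[s] @ L) / s2
        det = p11 * p22 - p12 * p12
        m1 = (p22 * b1 - p12 * b2) / det
        m2 = (p11 * b2 - p12 * b1) / det
        # sample via Cholesky of the 2x2 covariance (= inverse precision)
        l11 = np.sqrt(p22 / det)
        l21 = -p12 / det / l11
        l22 = np.sqrt(p11 / det - l21 ** 2)
        z1, z2 = rng.standard_normal(2)
        p["eta1"][s] = m1 + l11 * z1
        p["eta2"][s] = m2 + l21 * z1 + l22 * z2
        # σ_s | c, η — slice on log σ
        resid2 = float(((c[s] - p["eta1"][s] - p["eta2"][s] * L) ** 2).sum())
        scale = ss[s]

        def logf(ls, resid2=resid2, n=S, scale=scale):
            sig = np.exp(ls)
            return (-0.5 * resid2 / sig ** 2 - n * ls
                    - 0.5 * (sig / scale) ** 2 + ls)

        p["lsig"][s] = _slice_sample(logf, float(p["lsig"][s]), rng)

    for key, ekey, scale in (("lsig_pool", "eps_pool", priors.sigma_pool_scale),
                             ("lsig_time", "eps_time", priors.sigma_time_scale)):
        ee = p[ekey]
        resid2, n = float((ee ** 2).sum()), len(ee)

        def logf(ls, resid2=resid2, n=n, scale=scale):
            sig = np.exp(ls)
            return (-0.5 * resid2 / sig ** 2 - n * ls
                    - 0.5 * (sig / scale) ** 2 + ls)

        p[key][0] = _slice_sample(logf, float(p[key][0]), rng)


def _conditional_map(dyn_logp_grad, x0: np.ndarray, maxiter: int = 400):
    """L-BFGS mode of the conditional posterior of the gradient block."""
    from scipy.optimize import minimize

    def negf(x):
        lp, g = dyn_logp_grad(x)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(x)
        return -lp, -g

    res = minimize(negf, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "maxcor": 25})
    return res.x if np.isfinite(res.fun) else x0


def _dense_hessian(dyn_logp_grad, x: np.ndarray, h: float = 1e-4):
    """Dense negative Hessian at x from one gradient difference per axis."""
    _, g0 = dyn_logp_grad(x)
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        xp = x.copy()
        xp[i] += h
        _, gp = dyn_logp_grad(xp)
        H[:, i] = -(gp - g0) / h
    H = 0.5 * (H + H.T)
    H[~np.isfinite(H)] = 0.0
    return H


def _asis_scale_sweep(theta, layout, priors, length_std, logp_fn, rng,
                      steps: np.ndarray, adapt: bool) -> None:
    """Non-centered rescaling moves for the hierarchy SDs (ASIS step).

    The centered σ update (slice on σ | coefficients) mixes poorly for
    weakly identified families because the residual spread and σ are
    locked together.  This sweep proposes log σ jointly with a rescaling
    of the coefficients around their family mean — holding the
    standardized residuals fixed — which leaves the likelihood nearly
    flat for weak families and lets σ jump at the prior scale.  Target
    density in the non-centered parametrization adds the Jacobian S·log σ.
    """
    p = layout.unpack(theta)
    L = np.asarray(length_std, float)
    ss = np.broadcast_to(np.asarray(priors.sigma_scale, float), (32,))
    S = layout.S
    lp0 = logp_fn(theta)

    def hn_logpdf(ls, scale):
        return -0.5 * (np.exp(ls) / scale) ** 2 + ls

    for s in range(32):
        ls = float(p["lsig"][s])
        mu = p["eta1"][s] + p["eta2"][s] * L
        prop = ls + steps[s] * rng.standard_normal()
        th2 = theta.copy()
        p2 = layout.unpack(th2)
        p2["c"][s] = mu + np.exp(prop - ls) * (p["c"][s] - mu)
        p2["lsig"][s] = prop
        lp1 = logp_fn(th2)
        # centered-density ratio + non-centered Jacobian S·(ls' − ls);
        # the centered lp already contains the prior and −S·log σ terms
        log_acc = (lp1 - lp0) + S * (prop - ls)
        acc = np.exp(min(log_acc, 0.0)) if np.isfinite(lp1) else 0.0
        if rng.random() < acc:
            theta[:] = th2
            p = layout.unpack(theta)
            lp0 = lp1
        if adapt:
            steps[s] = float(np.clip(steps[s] * np.exp(0.3 * (acc - 0.44)),
                                     1e-3, 5.0))

    # family-mean and length-slope translations: move every coefficient of
    # a family together with its η, leaving the fourth-corner residuals
    # unchanged — the within-family prior is invariant, so acceptance is
    # driven by the likelihood and the η prior alone
    for s in range(32):
        k = 34 + s
        d1, d2 = steps[k] * rng.standard_normal(2)
        th2 = theta.copy()
        p2 = layout.unpack(th2)
        p2["c"][s] += d1 + d2 * L
        p2["eta1"][s] += d1
        p2["eta2"][s] += d2
        lp1 = logp_fn(th2)
        acc = np.exp(min(lp1 - lp0, 0.0)) if np.isfinite(lp1) else 0.0
        if rng.random() < acc:
            theta[:] = th2
            p = layout.unpack(theta)
            lp0 = lp1
        if adapt:
            steps[k] = float(np.clip(steps[k] * np.exp(0.3 * (acc - 0.44)),
                                     1e-3, 5.0))

    # paired moves along main-channel/floodplain offset combinations
    # (e.g. shift the Ricker decay while keeping the floodplain sum fixed)
    for j, (s1, s2) in enumerate(((0, 2), (1, 3))):      # (β1,β3), (β2,β4)
        k = 66 + j
        delta = steps[k] * rng.standard_normal()
        th2 = theta.copy()
        p2 = layout.unpack(th2)
        p2["c"][s1] += delta
        p2["eta1"][s1] += delta
        p2["c"][s2] -= delta
        p2["eta1"][s2] -= delta
        lp1 = logp_fn(th2)
        acc = np.exp(min(lp1 - lp0, 0.0)) if np.isfinite(lp1) else 0.0
        if rng.random() < acc:
            theta[:] = th2
            p = layout.unpack(theta)
            lp0 = lp1
        if adapt:
            steps[k] = float(np.clip(steps[k] * np.exp(0.3 * (acc - 0.44)),
                                     1e-3, 5.0))

    for j, (key, ekey, scale, n) in enumerate((
            ("lsig_pool", "eps_pool", priors.sigma_pool_scale, layout.P),
            ("lsig_time", "eps_time", priors.sigma_time_scale, layout.Y))):
        ls = float(p[key][0])
        prop = ls + steps[32 + j] * rng.standard_normal()
        th2 = theta.copy()
        p2 = layout.unpack(th2)
        p2[ekey][:] = np.exp(prop - ls) * p[ekey]
        p2[key][0] = prop
        lp1 = logp_fn(th2)
        log_acc = (lp1 - lp0) + n * (prop - ls)
        acc = np.exp(min(log_acc, 0.0)) if np.isfinite(lp1) else 0.0
        if rng.random() < acc:
            theta[:] = th2
            p = layout.unpack(theta)
            lp0 = lp1
        if adapt:
            steps[32 + j] = float(np.clip(
                steps[32 + j] * np.exp(0.3 * (acc - 0.44)), 1e-3, 5.0))


def _blocked_chain(logp_grad, theta0: np.ndarray, cfg: MCMCConfig,
                   rng: np.random.Generator, layout, priors, length_std,
                   logp_only=None, warm_start=None):
    """Default chain: NUTS on coefficients/effects/family means, slice-Gibbs
    on the hierarchy SDs.

    The gradient block (species coefficients, random effects, effort
    parameters, and the family means η1/η2) is preconditioned with a dense
    metric M = H_like + P_prior(σ), where H_like is the likelihood part of
    the Hessian measured once at the conditional mode (independent of the
    hierarchy SDs) and P_prior is the exact Gaussian prior precision of
    the block — including the c–η coupling — rebuilt after every Gibbs
    sweep.  NUTS runs in the whitened space v = Lᵀx (M = LLᵀ), which stays
    near unit scale while the SDs move, so family means of weakly
    identified coefficient families can jump at the prior scale instead of
    creeping at σ/√S per iteration.
    """
    from scipy.linalg import cholesky, solve_triangular

    S32 = layout.S
    n_c = 32 * S32
    n_p, n_y = layout.P, layout.Y
    L = np.asarray(length_std, float)
    sL, sL2 = float(L.sum()), float(L @ L)
    idx = np.concatenate([
        layout.dynamic,
        np.arange(*layout.slices["eta1"].indices(layout.dim)),
        np.arange(*layout.slices["eta2"].indices(layout.dim))])
    D = len(idx)
    o_eta1 = n_c + n_p + n_y + 5
    o_eta2 = o_eta1 + 32
    e1s = np.broadcast_to(np.asarray(priors.eta1_scale, float), (32,))
    e2s = np.broadcast_to(np.asarray(priors.eta2_scale, float), (32,))
    theta = theta0.copy()

    def dyn_logp_grad(x):
        th = theta.copy()
        th[idx] = x
        lp, g = logp_grad(th)
        return lp, g[idx]

    def prior_precision():
        p = layout.unpack(theta)
        P = np.zeros((D, D))
        inv2 = np.exp(-2.0 * p["lsig"])
        for s in range(32):
            pp = inv2[s]
            cs = slice(s * S32, (s + 1) * S32)
            di = np.arange(cs.start, cs.stop)
            P[di, di] += pp
            P[cs, o_eta1 + s] -= pp
            P[o_eta1 + s, cs] -= pp
            P[cs, o_eta2 + s] -= pp * L
            P[o_eta2 + s, cs] -= pp * L
            P[o_eta1 + s, o_eta1 + s] += S32 * pp + 1.0 / e1s[s] ** 2
            P[o_eta2 + s, o_eta2 + s] += sL2 * pp + 1.0 / e2s[s] ** 2
            P[o_eta1 + s, o_eta2 + s] += sL * pp
            P[o_eta2 + s, o_eta1 + s] += sL * pp
        di = np.arange(n_c, n_c + n_p)
        P[di, di] += np.exp(-2.0 * p["lsig_pool"][0])
        di = np.arange(n_c + n_p, n_c + n_p + n_y)
        P[di, di] += np.exp(-2.0 * p["lsig_time"][0])
        di = np.arange(n_c + n_p + n_y, n_c + n_p + n_y + 5)
        P[di, di] += 1.0          # logit-scale curvature for υ, ς
        return P

    x = theta[idx].copy()
    lp, gx = dyn_logp_grad(x)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite initial log-posterior")
    if warm_start is None:
        x = _conditional_map(dyn_logp_grad, x)
        H = _dense_hessian(dyn_logp_grad, x)
        H_like = H - prior_precision()
        ev, Q = np.linalg.eigh(0.5 * (H_like + H_like.T))
        H_like = (Q * np.clip(ev, 0.0, None)[None, :]) @ Q.T
        warm_start = {"x_map": x.copy(), "H_like": H_like}
    else:
        x = warm_start["x_map"].copy()
        H_like = warm_start["H_like"]

    def whitener():
        M = H_like + prior_precision()
        try:
            return cholesky(M, lower=True)
        except np.linalg.LinAlgError:
            return cholesky(M + 1e-6 * np.eye(D) * np.trace(M) / D, lower=True)

    Lw = whitener()
    x = x + cfg.init_jitter * solve_triangular(Lw.T, rng.standard_normal(D))
    lp, gx = dyn_logp_grad(x)
    if not np.isfinite(lp):
        x = theta[idx]
    theta[idx] = x
    inv_mass = np.ones(D)
    step = 0.3
    da = _dual_averaging_state(step, cfg.target_accept)
    draws = np.empty((cfg.n_draws, layout.dim))
    n_accept = 0.0
    asis_steps = np.full(68, 0.5)

    lp_fast = logp_only if logp_only is not None else (lambda th: logp_grad(th)[0])

    for it in range(cfg.n_warmup + cfg.n_draws):
        for _ in range(cfg.gibbs_sweeps):
            _gibbs_hyper_sweep(theta, layout, priors, length_std, rng)
            if it % cfg.asis_every == 0:
                _asis_scale_sweep(theta, layout, priors, length_std, lp_fast,
                                  rng, asis_steps, adapt=it < cfg.n_warmup)
        Lw = whitener()                           # prior precision moved

        def white_logp_grad(v, Lw=Lw):
            lp_, g_ = dyn_logp_grad(solve_triangular(Lw.T, v))
            return lp_, solve_triangular(Lw, g_, lower=True)

        v = Lw.T @ theta[idx]
        lp, gv = white_logp_grad(v)
        v, lp, gv, acc = _nuts_transition(
            white_logp_grad, v, lp, gv, step, inv_mass,
            cfg.max_tree_depth, rng)
        theta[idx] = solve_triangular(Lw.T, v)
        if it < cfg.n_warmup:
            step = _dual_averaging_update(da, acc)
            if it == max(cfg.n_warmup // 2, cfg.n_warmup - 200):
                # refresh the likelihood Hessian in the typical set; the
                # mode-based estimate misjudges the nonlinear decay terms
                H = _dense_hessian(dyn_logp_grad, theta[idx])
                H_like = H - prior_precision()
                ev, Q = np.linalg.eigh(0.5 * (H_like + H_like.T))
                H_like = (Q * np.clip(ev, 0.0, None)[None, :]) @ Q.T
            if it == cfg.n_warmup - 1:
                step = float(np.exp(da["log_eps_bar"]))
        else:
            draws[it - cfg.n_warmup] = theta
            n_accept += acc
    return draws, n_accept / max(cfg.n_draws, 1), step, warm_start


def _rw_chain(logp, theta0: np.ndarray, cfg: MCMCConfig, rng: np.random.Generator):
    """Adaptive random-walk Metropolis (diagonal preconditioner) fallback."""
    dim = len(theta0)
    theta = theta0.copy()
    lp = logp(theta)
    if not np.isfinite(lp):
        raise RuntimeError("non-finite initial log-posterior")
    scale = 2.38 / np.sqrt(dim)
    sd = np.ones(dim)
    draws = np.empty((cfg.n_draws, dim))
    warm_buf: list[np.ndarray] = []
    n_accept = 0.0
    for it in range(cfg.n_warmup + cfg.n_draws):
        prop = theta + scale * sd * rng.standard_normal(dim)
        lp_prop = logp(prop)
        acc = min(1.0, float(np.exp(min(lp_prop - lp, 0.0)))) if np.isfinite(lp_prop) else 0.0
        if rng.random() < acc:
            theta, lp = prop, lp_prop
        if it < cfg.n_warmup:
            scale *= np.exp(2.0 * (acc - 0.3) / max(it + 1, 20) ** 0.6)
            warm_buf.append(theta.copy())
            if (it + 1) % max(cfg.n_warmup // 4, 25) == 0 and len(warm_buf) >= 20:
                var = np.var(np.asarray(warm_buf[len(warm_buf) // 2:]), axis=0)
                sd = np.where(var > 1e-12, np.sqrt(var), sd)
        else:
            draws[it - cfg.n_warmup] = theta
            n_accept += acc
    return draws, n_accept / max(cfg.n_draws, 1), scale


# ----------------------------------------------------------------------
@dataclass
class PosteriorSamples:
    """Multi-chain posterior draws with per-parameter diagnostics."""

    theta: np.ndarray            # (chain, draw, dim) unconstrained
    layout: ParameterLayout
    length_std: np.ndarray
    hyper: np.ndarray            # (chain, draw, n_hyper) natural scale
    hyper_names: list[str]
    diagnostics: pd.DataFrame    # rhat/ess for every free parameter
    accept_rate: np.ndarray
    config: MCMCConfig
    priors: PriorConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def hyper_diagnostics(self) -> pd.DataFrame:
        return self.diagnostics.loc[self.hyper_names]

    def parameters(self, chain: int, draw: int):
        """Natural-scale ModelParameters for one draw."""
        return self.layout.to_natural(self.theta[chain, draw], self.length_std)

    def iter_parameters(self, thin: int = 1):
        for c in range(self.n_chains):
            for d in range(0, self.n_draws, thin):
                yield self.parameters(c, d)

    def hyper_summary(self) -> pd.DataFrame:
        flat = self.hyper.reshape(-1, self.hyper.shape[-1])
        q = np.quantile(flat, [0.05, 0.5, 0.95], axis=0)
        out = pd.DataFrame({
            "mean": flat.mean(axis=0), "sd": flat.std(axis=0, ddof=1),
            "q5": q[0], "median": q[1], "q95": q[2]},
            index=pd.Index(self.hyper_names, name="parameter"))
        return out.join(self.hyper_diagnostics())

    def to_inference_data(self):
        """ArviZ InferenceData with named hyperparameter and raw draws.

        Self-describing container for downstream tooling; write it to disk
        with ``arviz.to_netcdf`` if a single-file archive is wanted.
        """
        hyper = {n: self.hyper[:, :, i]
                 for i, n in enumerate(self.hyper_names)}
        return az.from_dict(posterior=hyper,
                            attrs={"sampler": self.config.sampler,
                                   "seed": self.config.seed,
                                   "n_warmup": self.config.n_warmup})

    def to_dataframe(self) -> pd.DataFrame:
        """Flat named draws (one row per chain × draw), hyperparameters only."""
        c, d, h = self.hyper.shape
        df = pd.DataFrame(self.hyper.reshape(-1, h), columns=self.hyper_names)
        df.insert(0, "draw", np.tile(np.arange(d), c))
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        return df


def initial_theta(layout: ParameterLayout, rng: np.random.Generator,
                  jitter: float = 0.1) -> np.ndarray:
    """Spec initial point (η = 0, σ = 0.3, υ = 0.5, ς = 0.8), jittered."""
    theta = np.zeros(layout.dim)
    p = layout.unpack(theta)
    p["lsig"][:] = np.log(0.3)
    p["lsig_pool"][:] = np.log(0.3)
    p["lsig_time"][:] = np.log(0.3)
    p["x_ups"][:] = 0.0                       # υ = 0.5
    p["x_lm"][:] = np.log(0.8 / 0.2)          # ς = 0.8
    return theta + jitter * rng.standard_normal(layout.dim)


def run_mcmc(dataset, prior_config: PriorConfig | None = None,
             mcmc_config: MCMCConfig | None = None) -> PosteriorSamples:
    """Sample the joint posterior; reproducible given the config seed."""
    priors = prior_config or PriorConfig()
    cfg = mcmc_config or MCMCConfig()
    arrays = dataset if isinstance(dataset, ModelArrays) else ModelArrays.from_dataset(dataset)
    layout = ParameterLayout(arrays.n_species, arrays.n_pools, arrays.n_years)

    def logp_grad(th):
        return log_posterior_and_grad(th, arrays, priors, layout)

    def logp(th):
        return log_posterior(th, arrays, priors, layout)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains, rates = [], []
    warm = None
    for c in range(cfg.n_chains):
        rng = np.random.default_rng(seeds[c])
        theta0 = initial_theta(layout, rng, cfg.init_jitter)
        if cfg.sampler == "nuts":
            d, rate, _, warm = _blocked_chain(logp_grad, theta0, cfg, rng,
                                              layout, priors,
                                              arrays.length_std,
                                              logp_only=logp,
                                              warm_start=warm)
        elif cfg.sampler == "hmc":
            d, rate, _ = _hmc_chain(logp_grad, theta0, cfg, rng)
        else:
            d, rate, _ = _rw_chain(logp, theta0, cfg, rng)
        chains.append(d)
        rates.append(rate)
    theta = np.asarray(chains)

    hyper = np.empty((cfg.n_chains, cfg.n_draws, len(layout.hyper_names())))
    for c in range(cfg.n_chains):
        for i in range(cfg.n_draws):
            hyper[c, i] = layout.hyper_values(theta[c, i])
    names = layout.hyper_names()
    all_draws = np.concatenate([theta, hyper], axis=2)
    all_names = layout.param_names() + names
    diag = _diagnostics_table(all_draws, all_names)

    warns = []
    hd = diag.loc[names]
    bad_r = hd[hd["rhat"] > cfg.rhat_threshold]
    if len(bad_r):
        warns.append(f"{len(bad_r)} hyperparameter(s) with R-hat > "
                     f"{cfg.rhat_threshold}: max {bad_r['rhat'].max():.3f}")
    bad_e = hd[hd["ess"] < cfg.ess_min]
    if len(bad_e):
        warns.append(f"{len(bad_e)} hyperparameter(s) with ESS < "
                     f"{cfg.ess_min:g}: min {bad_e['ess'].min():.0f}")
    for w in warns:
        _warnings.warn(w, stacklevel=2)
    return PosteriorSamples(theta=theta, layout=layout,
                            length_std=arrays.length_std, hyper=hyper,
                            hyper_names=names, diagnostics=diag,
                            accept_rate=np.asarray(rates), config=cfg,
                            priors=priors, warnings=warns)
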