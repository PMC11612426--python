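"""Water-take management scenarios: depth rules, occupancy, distribution loss.

Two regulatory instruments are represented.  A *minimum-depth rule* for
direct pumping from main-channel pools draws every pool down to the rule
depth (pools already shallower are untouched): D' = min(D, rule).  A
*percent-reduction rule* for floodplain harvesting lowers every floodplain
pool proportionally: D' = D·(1 − f).  Both represent full extraction of
the legally available water.

A species occupies a pool with probability 1 − exp(−λ) under the Poisson
abundance model, so the expected breadth of distribution is the summed
occupancy over target pools.  Percent distribution loss compares the
scenario prediction against the no-extraction baseline *within* each
posterior draw; the loss is then summarized over draws (posterior mean
and 5–95% interval).  Losses can be negative — shallow-optimum species
gain pools under drawdown — and are never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ScalingInfo, SurveyDataset
from .likelihood import ModelParameters

DEFAULT_OBJECTIVES = (5.0, 10.0, 15.0)


@dataclass
class ScenarioSpec:
    """A water-take rule family evaluated over a grid."""

    kind: str                                   # "min_depth" | "percent_reduction"
    grid: np.ndarray | None = None
    objectives: tuple[float, ...] = DEFAULT_OBJECTIVES
    mesohabitat: int | None = None              # default: 0 for min_depth, 1 otherwise
    eps_policy: str = "posterior"               # "posterior" | "zero" | "marginalize"

    def __post_init__(self) -> None:
        if self.kind not in ("min_depth", "percent_reduction"):
            raise ValueError("kind must be 'min_depth' or 'percent_reduction'")
        if self.grid is None:
            if self.kind == "min_depth":
                self.grid = np.round(np.arange(0.5, 2.0 + 1e-9, 0.05), 10)
            else:
                self.grid = np.round(np.arange(0.0, 0.90 + 1e-9, 0.02), 10)
        self.grid = np.asarray(self.grid, float)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("rule grid must be strictly increasing")
        if self.mesohabitat is None:
            self.mesohabitat = 0 if self.kind == "min_depth" else 1
        if self.kind == "min_depth" and (self.grid < 0).any():
            raise ValueError("negative minimum-depth rule")
        if self.kind == "percent_reduction":
            if (self.grid < 0).any() or (self.grid > 1).any():
                raise ValueError("reduction fraction outside [0, 1]")
            if (self.grid > 0.9).any():
                warnings.warn("reduction fraction beyond the documented 0-0.9 range")


def apply_min_depth_rule(depths_m, rule_m: float) -> np.ndarray:
    """Draw pools deeper than the rule down to it; shallower pools untouched."""
    if rule_m < 0:
        raise ValueError("negative minimum-depth rule")
    return np.minimum(np.asarray(depths_m, float), rule_m)


def apply_percent_reduction(depths_m, fraction: float) -> np.ndarray:
    """Proportional drawdown D' = D·(1 − f)."""
    if not 0 <= fraction <= 1:
        raise ValueError("reduction fraction outside [0, 1]")
    if fraction > 0.9:
        warnings.warn("reduction fraction beyond the documented 0-0.9 range")
    return np.asarray(depths_m, float) * (1.0 - fraction)


# ----------------------------------------------------------------------
def pool_log_lambda(params: ModelParameters, pools: pd.DataFrame,
                    scaling: ScalingInfo, depths_m: np.ndarray,
                    eps_pool: np.ndarray) -> np.ndarray:
    """log λ (species × pools) at given raw depths, generic year (ε_time = 0).

    Depths are re-scaled with the frozen training divisor; zero depth maps
    to λ = 0 exactly.
    """
    D = scaling.scale_depth(depths_m)
    if (D < 0).any():
        raise ValueError("negative depth")
    b = params.beta.T                            # (10, S) -> broadcast
    M = pools["mesohabitat"].to_numpy(float)
    T = pools["turbidity_std"].to_numpy(float)
    S = pools["complexity_std"].to_numpy(float)
    R = pools["river_km_std"].to_numpy(float)
    with np.errstate(divide="ignore"):
        logD = np.log(D)
    return (b[0][:, None] + b[2][:, None] * M + logD[None, :]
            - np.exp(b[1][:, None] + b[3][:, None] * M) * D
            + b[4][:, None] * T + b[5][:, None] * (T * M)
            + b[6][:, None] * S + b[7][:, None] * (S * M)
            + b[8][:, None] * R + b[9][:, None] * (R * M)
            + eps_pool[None, :])


def expected_occupied_pools(params: ModelParameters, pools: pd.DataFrame,
                            scaling: ScalingInfo, depths_m=None,
                            eps_pool=None) -> np.ndarray:
    """Σ_pools P(N ≥ 1) = Σ_pools (1 − e^{−λ}) per species."""
    if depths_m is None:
        depths_m = pools["max_depth"].to_numpy(float)
    if eps_pool is None:
        eps_pool = np.zeros(len(pools))
    loglam = pool_log_lambda(params, pools, scaling, np.asarray(depths_m, float),
                             np.asarray(eps_pool, float))
    occ = -np.expm1(-np.exp(loglam))
    return occ.sum(axis=1)


def distribution_loss(baseline, scenario) -> np.ndarray:
    """Percent loss 100·(baseline − scenario)/baseline; NaN where baseline = 0."""
    baseline = np.asarray(baseline, float)
    scenario = np.asarray(scenario, float)
    out = np.full(baseline.shape, np.nan)
    ok = baseline > 0
    out[ok] = 100.0 * (baseline[ok] - scenario[ok]) / baseline[ok]
    if (~ok).any():
        warnings.warn("species with zero baseline distribution excluded "
                      "from objective counting")
    return out


# ----------------------------------------------------------------------
@dataclass
class ScenarioResult:
    """Per-species loss curves and objective attainment over a rule grid."""

    spec: ScenarioSpec
    species_ids: list[str]
    rules: np.ndarray
    baseline_mean: np.ndarray        # (S,) posterior-mean occupied pools
    scenario_mean: np.ndarray        # (S, R)
    loss_mean: np.ndarray            # (S, R) posterior-mean percent loss
    loss_q5: np.ndarray
    loss_q95: np.ndarray
    n_target_pools: int

    def loss_table(self) -> pd.DataFrame:
        """Tidy (species, rule) table of losses with credible intervals."""
        S, R = self.loss_mean.shape
        return pd.DataFrame({
            "species_id": np.repeat(self.species_ids, R),
            "rule": np.tile(self.rules, S),
            "baseline": np.repeat(self.baseline_mean, R),
            "scenario": self.scenario_mean.ravel(),
            "loss_pct": self.loss_mean.ravel(),
            "loss_q5": self.loss_q5.ravel(),
            "loss_q95": self.loss_q95.ravel(),
        })

    def objective_counts(self) -> pd.DataFrame:
        """Number of species meeting each loss objective at each rule."""
        rows = []
        for ri, rule in enumerate(self.rules):
            loss = self.loss_mean[:, ri]
            for obj in self.spec.objectives:
                rows.append((rule, obj, int((loss[~np.isnan(loss)] < obj).sum())))
        return pd.DataFrame(rows, columns=["rule", "objective_pct", "n_species"])

    def most_liberal_rule(self) -> pd.DataFrame:
        """Per species and objective, the most permissive rule still meeting it.

        For a minimum-depth rule the most liberal option is the *smallest*
        depth; for percent reduction it is the *largest* fraction.  NaN when
        no rule on the grid meets the objective (or baseline was zero).
        """
        rows = []
        for si, sp in enumerate(self.species_ids):
            for obj in self.spec.objectives:
                ok = np.where(self.loss_mean[si] < obj)[0]
                if len(ok) == 0 or np.isnan(self.loss_mean[si]).all():
                    rule = np.nan
                elif self.spec.kind == "min_depth":
                    rule = float(self.rules[ok.min()])
                else:
                    rule = float(self.rules[ok.max()])
                rows.append((sp, obj, rule))
        return pd.DataFrame(rows, columns=["species_id", "objective_pct", "rule"])


def _draw_losses(params: ModelParameters, pools, scaling, spec: ScenarioSpec,
                 eps_pool, rng=None):
    """(baseline (S,), scenario (S, R)) expected occupied pools for one draw."""
    depths = pools["max_depth"].to_numpy(float)
    base = expected_occupied_pools(params, pools, scaling, depths, eps_pool)
    scen = np.empty((len(base), len(spec.grid)))
    for ri, rule in enumerate(spec.grid):
        if spec.kind == "min_depth":
            d2 = apply_min_depth_rule(depths, rule)
        else:
            d2 = apply_percent_reduction(depths, rule)
        scen[:, ri] = expected_occupied_pools(params, pools, scaling, d2, eps_pool)
    return base, scen


def objective_curve(posterior, dataset: SurveyDataset, spec: ScenarioSpec,
                    thin: int = 1, seed: int = 0) -> ScenarioResult:
    """Evaluate the scenario over posterior draws (or a single parameter set).

    ``posterior`` is a PosteriorSamples or a single ModelParameters (a
    posterior collapsed to a point).  Target pools are those of the
    scenario's mesohabitat; their sampled random effects come from each
    draw (``eps_policy='posterior'``), are zeroed, or are re-drawn from
    Normal(0, σ_pool) for unsampled-pool marginalization.
    """
    sel = dataset.pools["mesohabitat"].to_numpy() == spec.mesohabitat
    if not sel.any():
        raise ValueError("no pools in the target mesohabitat")
    pools = dataset.pools.loc[sel].reset_index(drop=True)
    scaling = dataset.scaling
    if scaling is None:
        raise ValueError("dataset must carry frozen scaling constants")
    rng = np.random.default_rng(seed)

    if isinstance(posterior, ModelParameters):
        draws = [posterior]
    else:
        draws = list(posterior.iter_parameters(thin=thin))
    S = draws[0].beta.shape[0]
    R = len(spec.grid)
    base_d = np.empty((len(draws), S))
    scen_d = np.empty((len(draws), S, R))
    for di, params in enumerate(draws):
        if spec.eps_policy == "posterior":
            eps = params.eps_pool[sel]
        elif spec.eps_policy == "zero":
            eps = np.zeros(sel.sum())
        elif spec.eps_policy == "marginalize":
            eps = rng.normal(0.0, params.sigma_pool, sel.sum())
        else:
            raise ValueError(f"unknown eps_policy {spec.eps_policy!r}")
        base_d[di], scen_d[di] = _draw_losses(params, pools, scaling, spec, eps)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loss_d = 100.0 * (base_d[:, :, None] - scen_d) / base_d[:, :, None]
        loss_d[np.broadcast_to(base_d[:, :, None] <= 0, loss_d.shape)] = np.nan
        loss_mean = np.nanmean(loss_d, axis=0)
        loss_q5 = np.nanquantile(loss_d, 0.05, axis=0)
        loss_q95 = np.nanquantile(loss_d, 0.95, axis=0)
    if np.isnan(loss_d).any():
        warnings.warn("species with zero baseline distribution excluded "
                      "from objective counting")
    return ScenarioResult(
        spec=spec, species_ids=list(dataset.species["species_id"]),
        rules=spec.grid, baseline_mean=base_d.mean(axis=0),
        scenario_mean=scen_d.mean(axis=0),
        loss_mean=loss_mean, loss_q5=loss_q5, loss_q95=loss_q95,
        n_target_pools=int(sel.sum()))
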