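"""Results object: posterior summaries, diagnostics, predictions, reports."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .evaluation import FidelityReport, fidelity, ppc_totals, predictive_detection_prob
from .inference import PosteriorSamples
from .likelihood import FAMILIES, peak_depth
from .scenarios import ScenarioResult, ScenarioSpec, objective_curve


class PoolAbundanceResults:
    """Posterior of a fitted PoolAbundanceModel with reporting helpers."""

    def __init__(self, model, posterior: PosteriorSamples):
        self.model = model
        self.posterior = posterior

    # ------------------------------------------------------------------
    @property
    def converged(self) -> bool:
        d = self.posterior.hyper_diagnostics()
        return bool((d["rhat"] < self.posterior.config.rhat_threshold).all()
                    and (d["ess"] > self.posterior.config.ess_min).all())

    def summary(self, full: bool = False) -> pd.DataFrame:
        """Posterior mean/SD/quantiles and diagnostics per hyperparameter."""
        s = self.posterior.hyper_summary()
        return s if full else s.loc[[n for n in s.index if not n.startswith("z")]]

    def hyper_draws(self, name: str) -> np.ndarray:
        """(chain, draw) array for one named hyperparameter."""
        idx = self.posterior.hyper_names.index(name)
        return self.posterior.hyper[:, :, idx]

    def coefficient_draws(self, family: str) -> np.ndarray:
        """(chain*draw, species) natural-scale coefficients of one family."""
        if family not in FAMILIES:
            raise KeyError(family)
        out = [params.coeff(family)
               for params in self.posterior.iter_parameters()]
        return np.asarray(out)

    def peak_depth_summary(self) -> pd.DataFrame:
        """Posterior mean depth of maximum abundance per species, in metres."""
        rows = []
        div = self.model.dataset.scaling.depth_divisor
        for params in self.posterior.iter_parameters():
            rows.append([peak_depth(params.beta[:, 1]),
                         peak_depth(params.beta[:, 1], params.beta[:, 3], M=1)])
        arr = np.asarray(rows) * div          # (draws, 2, S) scaled -> metres
        return pd.DataFrame({
            "species_id": self.model.dataset.species["species_id"],
            "peak_depth_mc_m": arr[:, 0, :].mean(axis=0),
            "peak_depth_fp_m": arr[:, 1, :].mean(axis=0),
        }).set_index("species_id")

    # ------------------------------------------------------------------
    def predict_scenario(self, spec: ScenarioSpec | str, thin: int = 1,
                         **spec_kwargs) -> ScenarioResult:
        """Run a water-take scenario (kind name or full ScenarioSpec)."""
        if isinstance(spec, str):
            spec = ScenarioSpec(kind=spec, **spec_kwargs)
        return objective_curve(self.posterior, self.model.dataset, spec, thin=thin)

    def predictive_probs(self, thin: int = 1) -> np.ndarray:
        return predictive_detection_prob(self.posterior, self.model.dataset,
                                         thin=thin)

    def fidelity(self, threshold: float = 0.5, thin: int = 1,
                 ppc_reps: int = 0, seed: int = 0) -> FidelityReport:
        """Within-sample detection accuracy (optionally with PPC p-values)."""
        probs = self.predictive_probs(thin=thin)
        report = fidelity(probs, self.model.dataset, threshold=threshold)
        if ppc_reps:
            report.ppc_pvalues = ppc_totals(self.posterior, self.model.dataset,
                                            n_rep=ppc_reps, seed=seed)
        return report

    def ppc_totals(self, n_rep: int = 200, seed: int = 0) -> pd.Series:
        return ppc_totals(self.posterior, self.model.dataset, n_rep=n_rep,
                          seed=seed)

    # ------------------------------------------------------------------
    def plot_depth_response(self, mesohabitat: int = 0, n_depth: int = 100,
                            ax=None):
        """Posterior-mean λ(depth) per species on the raw depth scale."""
        import matplotlib.pyplot as plt

        from .scenarios import pool_log_lambda

        scaling = self.model.dataset.scaling
        depths = np.linspace(1e-3, scaling.depth_divisor, n_depth)
        grid = pd.DataFrame({
            "mesohabitat": mesohabitat, "turbidity_std": 0.0,
            "complexity_std": 0.0, "river_km_std": 0.0}, index=range(n_depth))
        acc = 0.0
        n = 0
        for params in self.posterior.iter_parameters():
            acc += np.exp(pool_log_lambda(params, grid, scaling, depths,
                                          np.zeros(n_depth)))
            n += 1
        lam = acc / n
        if ax is None:
            _, ax = plt.subplots()
        for si, sp in enumerate(self.model.dataset.species["species_id"]):
            ax.plot(depths, lam[si], label=sp, lw=1)
        ax.set_xlabel("maximum pool depth (m)")
        ax.set_ylabel("expected abundance λ")
        return ax

    def save(self, out_dir: str) -> None:
        """Write draws, summary, diagnostics and run metadata as text files."""
        from ._posterior_io import save_theta

        os.makedirs(out_dir, exist_ok=True)
        self.posterior.to_dataframe().to_csv(
            os.path.join(out_dir, "posterior_draws.csv"), index=False)
        save_theta(self.posterior, out_dir)
        self.summary().to_csv(os.path.join(out_dir, "posterior_summary.csv"))
        self.posterior.diagnostics.to_csv(os.path.join(out_dir, "diagnostics.csv"))
        cfg = self.posterior.config
        scaling = self.model.dataset.scaling
        meta = {
            "n_species": self.model.dataset.n_species,
            "n_visits": self.model.dataset.n_visits,
            "removed_species": self.model.removed_species,
            "mcmc": {k: getattr(cfg, k) for k in
                     ("n_chains", "n_warmup", "n_draws", "seed", "sampler")},
            "priors": {k: np.asarray(getattr(self.posterior.priors, k)).tolist()
                       for k in ("eta1_loc", "eta1_scale", "eta2_loc",
                                 "eta2_scale", "sigma_scale",
                                 "sigma_pool_scale", "sigma_time_scale")},
            "scaling": {"depth_divisor": scaling.depth_divisor,
                        "sample_depth_divisor": scaling.sample_depth_divisor,
                        "effort_divisor": scaling.effort_divisor,
                        "center": scaling.center, "sd": scaling.sd},
            "accept_rate": self.posterior.accept_rate.tolist(),
            "warnings": self.posterior.warnings,
        }
        with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
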