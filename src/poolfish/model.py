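"""User-facing model class tying the pipeline together.

Typical use::

    from poolfish import PoolAbundanceModel, synthetic

    ds = synthetic.simulate("fitzroy_small", seed=1)
    model = PoolAbundanceModel(ds)
    res = model.fit(chains=4, draws=500, warmup=500, seed=1)
    print(res.summary())
    scen = res.predict_scenario("min_depth")
"""

from __future__ import annotations

import numpy as np

from .data import SurveyDataset, filter_rare_species, load_survey, scale_covariates
from .engine import (ModelArrays, ParameterLayout, loglik_total,
                     natural_log_posterior)
from .inference import MCMCConfig, PriorConfig, run_mcmc
from .likelihood import ModelParameters
from .results import PoolAbundanceResults


class PoolAbundanceModel:
    """Hierarchical multi-species, multi-gear detection model of pool fish.

    Parameters
    ----------
    dataset : SurveyDataset
        A validated survey.  Covariates are scaled on construction if the
        dataset does not already carry frozen scaling constants.
    priors : PriorConfig, optional
        Hyperprior settings; defaults are mildly informative.
    min_events : int
        Rare-species filter threshold: species detected at fewer than this
        many site-visits are removed before fitting (default 3, i.e.
        species caught at two or fewer events are dropped).
    """

    def __init__(self, dataset: SurveyDataset, priors: PriorConfig | None = None,
                 min_events: int = 3):
        dataset, removed = filter_rare_species(dataset, min_events=min_events)
        if dataset.n_species == 0:
            raise ValueError("no species left after the rare-species filter; "
                             "lower min_events")
        if not dataset.is_scaled:
            dataset = scale_covariates(dataset)
        self.dataset = dataset
        self.removed_species = removed
        self.priors = priors or PriorConfig()
        self.arrays = ModelArrays.from_dataset(dataset)
        self.layout = ParameterLayout(self.arrays.n_species,
                                      self.arrays.n_pools, self.arrays.n_years)

    @classmethod
    def from_tables(cls, tables_path: str, config: dict | None = None,
                    **kwargs) -> "PoolAbundanceModel":
        """Build from the five survey CSVs on disk."""
        return cls(load_survey(tables_path, config), **kwargs)

    # ------------------------------------------------------------------
    @property
    def n_free_parameters(self) -> int:
        return self.layout.dim

    def loglike(self, params: ModelParameters) -> float:
        """Marginalized detection log-likelihood at natural-scale parameters."""
        return loglik_total(params, self.arrays)

    def logposterior(self, params: ModelParameters) -> float:
        """Natural-scale unnormalized log posterior (likelihood + priors)."""
        return natural_log_posterior(params, self.arrays, self.priors)

    def fit(self, chains: int = 4, draws: int = 500, warmup: int = 500,
            seed: int = 0, sampler: str = "nuts",
            **config_kwargs) -> PoolAbundanceResults:
        """Sample the posterior and return a results object."""
        cfg = MCMCConfig(n_chains=chains, n_draws=draws, n_warmup=warmup,
                         seed=seed, sampler=sampler, **config_kwargs)
        posterior = run_mcmc(self.arrays, self.priors, cfg)
        return PoolAbundanceResults(self, posterior)

    def simulate(self, truth, seed: int = 0) -> SurveyDataset:
        """Replace detections with a fresh simulation at ``truth`` parameters."""
        from .synthetic import simulate_survey
        return simulate_survey(self.dataset, truth, seed=seed)
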