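"""Round-trip of posterior draws through plain CSV for the CLI pipeline."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .engine import ParameterLayout
from .inference import MCMCConfig, PosteriorSamples, _diagnostics_table


def save_theta(posterior: PosteriorSamples, out_dir: str) -> None:
    """Write the full unconstrained draws (one row per chain × draw)."""
    c, d, dim = posterior.theta.shape
    df = pd.DataFrame(posterior.theta.reshape(-1, dim),
                      columns=posterior.layout.param_names())
    df.insert(0, "draw", np.tile(np.arange(d), c))
    df.insert(0, "chain", np.repeat(np.arange(c), d))
    df.to_csv(os.path.join(out_dir, "theta_draws.csv"), index=False)


def load_posterior(path: str, model) -> PosteriorSamples:
    """Rebuild a PosteriorSamples from `theta_draws.csv` written by save().

    The layout comes from ``model`` (the same filtered, scaled dataset must
    be supplied); diagnostics are recomputed from the loaded draws.
    """
    df = pd.read_csv(os.path.join(path, "theta_draws.csv"))
    layout: ParameterLayout = model.layout
    names = layout.param_names()
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise ValueError(f"posterior file lacks parameter column(s) {missing[:3]}"
                         " — was it fitted to a different dataset?")
    chains = np.sort(df["chain"].unique())
    theta = np.stack([df.loc[df["chain"] == c, names].to_numpy(float)
                      for c in chains])
    hyper_names = layout.hyper_names()
    hyper = np.empty((theta.shape[0], theta.shape[1], len(hyper_names)))
    for c in range(theta.shape[0]):
        for i in range(theta.shape[1]):
            hyper[c, i] = layout.hyper_values(theta[c, i])
    diag = _diagnostics_table(np.concatenate([theta, hyper], axis=2),
                              names + hyper_names)
    return PosteriorSamples(theta=theta, layout=layout,
                            length_std=model.arrays.length_std, hyper=hyper,
                            hyper_names=hyper_names, diagnostics=diag,
                            accept_rate=np.full(theta.shape[0], np.nan),
                            config=MCMCConfig(n_chains=max(2, theta.shape[0])),
                            priors=model.priors)
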