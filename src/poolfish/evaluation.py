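"""Posterior-predictive checks and the model-fidelity metric.

Fidelity here is thresholded posterior-mean detection accuracy: the
posterior-mean marginal probability of detecting a species in a sample is
compared against 0.5 (configurable) and scored against the observed 0/1
detection, per species and pooled.  This is this package's definition of
prediction accuracy for detection/non-detection data; it is computed
within-sample (no cross-validation).

The marginal per-sample detection probability integrates the latent
abundance out within each draw:

    p̄ = 1 − Σ_N Poisson(N | λ) (1 − r)^N

evaluated by the same truncated-sum machinery as the likelihood (the
closed form 1 − e^{−λr} serves as an independent oracle in the tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .data import GEARS, SurveyDataset
from .engine import ModelArrays, latent_state
from .likelihood import ModelParameters, choose_n_max


def _marginal_sample_probs(params: ModelParameters, arrays: ModelArrays) -> np.ndarray:
    """Within-draw marginal detection probability per (species, sample)."""
    loglam, r = latent_state(params, arrays)
    lam = np.exp(loglam)
    n_max = choose_n_max(float(lam.max()) if lam.size else 0.0)
    N = np.arange(n_max + 1.0)
    log_pois = (N[None, None, :] * loglam[:, :, None] - lam[:, :, None]
                - gammaln(N + 1.0)[None, None, :])
    l1p = np.log1p(-np.minimum(r, 1 - 1e-12))                    # (S, K)
    # log Σ_N Pois(N|λ_v) (1−r_k)^N for the sample's visit
    log_nondet = logsumexp(log_pois[:, arrays.visit_of, :]
                           + N[None, None, :] * l1p[:, :, None], axis=2)
    return -np.expm1(log_nondet)


def predictive_detection_prob(posterior, dataset: SurveyDataset,
                              thin: int = 1) -> np.ndarray:
    """Posterior-mean marginal detection probability, (species, samples).

    ``posterior`` may be a PosteriorSamples or a single ModelParameters.
    Sample columns follow the samples-table row order.
    """
    arrays = ModelArrays.from_dataset(dataset)
    if isinstance(posterior, ModelParameters):
        return _marginal_sample_probs(posterior, arrays)
    acc = None
    n = 0
    for params in posterior.iter_parameters(thin=thin):
        p = _marginal_sample_probs(params, arrays)
        acc = p if acc is None else acc + p
        n += 1
    return acc / n


@dataclass
class FidelityReport:
    """Detection-accuracy summary of a fitted model."""

    per_species: pd.DataFrame        # accuracy_pct, n_cells, detections
    overall_accuracy: float          # percent, pooled over species × samples
    threshold: float
    gear_calibration: pd.DataFrame   # observed vs predicted frequency per gear
    ppc_pvalues: pd.Series | None = None

    def __str__(self) -> str:
        lines = [f"overall accuracy: {self.overall_accuracy:.1f}% "
                 f"(threshold {self.threshold})",
                 f"species range: {self.per_species['accuracy_pct'].min():.1f}"
                 f"-{self.per_species['accuracy_pct'].max():.1f}%"]
        return "\n".join(lines)


def fidelity(probs: np.ndarray, dataset: SurveyDataset,
             threshold: float = 0.5) -> FidelityReport:
    """Score thresholded detection predictions against the observed data."""
    arrays = ModelArrays.from_dataset(dataset)
    y = arrays.y
    if probs.shape != y.shape:
        raise ValueError("probability/observation shape mismatch")
    if y.size == 0:
        raise ValueError("empty detection data")
    hit = (probs >= threshold).astype(int) == y
    per_sp = pd.DataFrame({
        "species_id": dataset.species["species_id"],
        "accuracy_pct": 100.0 * hit.mean(axis=1),
        "n_cells": y.shape[1],
        "detections": y.sum(axis=1),
    }).set_index("species_id")
    gear_rows = []
    for g in GEARS:
        sel = arrays.gear_sel[g]
        if sel.any():
            gear_rows.append((g, int(sel.sum()), float(y[:, sel].mean()),
                              float(probs[:, sel].mean())))
    cal = pd.DataFrame(gear_rows, columns=["gear", "n_samples",
                                           "observed_freq", "predicted_freq"])
    return FidelityReport(per_species=per_sp,
                          overall_accuracy=float(100.0 * hit.mean()),
                          threshold=threshold, gear_calibration=cal)


def ppc_totals(posterior, dataset: SurveyDataset, n_rep: int = 200,
               seed: int = 0) -> pd.Series:
    """Posterior-predictive p-values for per-species detection totals.

    Each replicate re-simulates N ~ Poisson(λ) and y ~ Bernoulli(p) from a
    posterior draw (cycled over draws); the p-value is the fraction of
    replicate totals ≥ the observed total (ties counted as exceedances).
    """
    if n_rep < 10:
        raise ValueError("need at least 10 posterior-predictive replicates")
    arrays = ModelArrays.from_dataset(dataset)
    obs = arrays.y.sum(axis=1)
    rng = np.random.default_rng(seed)
    if isinstance(posterior, ModelParameters):
        draws = [posterior]
    else:
        draws = list(posterior.iter_parameters(
            thin=max(1, (posterior.n_chains * posterior.n_draws) // n_rep)))
    exceed = np.zeros(arrays.n_species)
    for rep in range(n_rep):
        params = draws[rep % len(draws)]
        loglam, r = latent_state(params, arrays)
        N = rng.poisson(np.exp(loglam))
        p = -np.expm1(N[:, arrays.visit_of]
                      * np.log1p(-np.minimum(r, 1 - 1e-12)))
        tot = (rng.random(p.shape) < p).sum(axis=1)
        exceed += tot >= obs
    return pd.Series(exceed / n_rep, index=dataset.species["species_id"],
                     name="ppc_pvalue")
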