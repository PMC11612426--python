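import warnings

import numpy as np
import pytest

from poolfish import PoolAbundanceModel, synthetic
from poolfish.data import GEARS
from poolfish.engine import ModelArrays


@pytest.fixture(scope="session")
def tiny_dataset():
    return synthetic.simulate("tiny", seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """fitzroy_small survey with known truth (12 species, 30 pools)."""
    return synthetic.simulate("fitzroy_small", seed=1)


@pytest.fixture(scope="session")
def small_arrays(small_dataset):
    return ModelArrays.from_dataset(small_dataset)


@pytest.fixture(scope="session")
def recovery_fit(small_dataset):
    """One four-chain fit of the fitzroy_small survey, shared across tests.

    This is the expensive fixture: it runs the full fitting protocol once
    and is reused by the recovery, convergence and reporting checks.
    """
    model = PoolAbundanceModel(small_dataset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = model.fit(chains=4, draws=500, warmup=250, seed=7)
    return model, results


def prior_only_arrays(n_species=3, n_pools=2, n_years=1,
                      length_std=None) -> ModelArrays:
    """A degenerate survey with no visits: the posterior is the prior."""
    S = n_species
    if length_std is None:
        length_std = np.linspace(-1, 1, S)
    return ModelArrays(
        n_species=S, n_pools=n_pools, n_visits=0, n_years=n_years,
        n_samples=0, length_std=np.asarray(length_std, float),
        pool_idx=np.zeros(0, int), year_idx=np.zeros(0, int),
        M=np.zeros(0), D=np.zeros(0), logD=np.zeros(0), T=np.zeros(0),
        Sc=np.zeros(0), R=np.zeros(0), C=np.zeros(0),
        visit_of=np.zeros(0, int), gear_of=np.zeros(0, int),
        Dk=np.zeros(0), logDk=np.zeros(0), Sk=np.zeros(0), E=np.zeros(0),
        logE=np.zeros(0), lm5=np.zeros(0, bool),
        y=np.zeros((S, 0), np.int8), vis_ind=np.zeros((0, 0)),
        gear_sel={g: np.zeros(0, bool) for g in GEARS},
        det_i=np.zeros(0, int), det_k=np.zeros(0, int),
        det_u=np.zeros(0, int))
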