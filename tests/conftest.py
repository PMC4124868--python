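"""Shared fixtures: the reference bond and cached simulation ensembles.

The reference parameters (10 k_B T barrier at 300 K, 1 nm range,
1000 nm^2/s diffusivity) are used throughout; expensive Brownian-dynamics
ensembles are session-scoped so several tests can share one run.
"""

import numpy as np
import pytest

from rapidfs import (
    BondModel,
    LoadingProtocol,
    SimulationConfig,
    simulate_ruptures,
)


@pytest.fixture(scope="session")
def ref_model() -> BondModel:
    return BondModel.from_kT(10.0, 1.0, 1000.0, temperature=300.0)


@pytest.fixture(scope="session")
def sim_5000(ref_model):
    """Factory for cached 5000-trajectory ensembles at a given field rate."""
    cache = {}

    def _get(rate: float):
        if rate not in cache:
            cache[rate] = simulate_ruptures(
                ref_model,
                LoadingProtocol.field(rate),
                SimulationConfig(n=5000, seed=20_200 + int(np.log10(rate))),
            )
        return cache[rate]

    return _get


@pytest.fixture(scope="session")
def global_fit(recovery_dataset):
    """Session-wide global MLE fit of the recovery ensemble."""
    from rapidfs import fit_mle

    return fit_mle(recovery_dataset, n_restarts=6, seed=17)


@pytest.fixture(scope="session")
def recovery_dataset(ref_model):
    """Multi-rate ensemble for the global-fit recovery experiment.

    400 ruptures per decade of loading rate from 1e2 to 1e9 pN/s, simulated
    at the reference ground truth.
    """
    dataset = None
    for i, exponent in enumerate(range(2, 10)):
        part = simulate_ruptures(
            ref_model,
            LoadingProtocol.field(10.0 ** exponent),
            SimulationConfig(n=400, seed=31_000 + i),
        )
        dataset = part if dataset is None else dataset.merged(part)
    return dataset
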