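"""Shared fixtures: small synthetic datasets reused across test modules."""

import pytest

from ifnsynergy.synthetic import SimulationParams, simulate_all


@pytest.fixture(scope="session")
def noiseless_small():
    """Small noiseless dataset: every stage must recover truth exactly."""
    params = SimulationParams(
        seed=11,
        n_peaks=60,
        n_genes=360,
        n_isgs=40,
        chip_noise_sigma=0.0,
        nb_dispersion=0.0,
    )
    return params, simulate_all(params)


@pytest.fixture(scope="session")
def noisy_small():
    """Small dataset at the default noise levels."""
    params = SimulationParams(seed=12, n_peaks=60, n_genes=360, n_isgs=40)
    return params, simulate_all(params)
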