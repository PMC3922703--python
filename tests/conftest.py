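import numpy as np
import pandas as pd
import pytest

from microfunc import SimulationConfig, build_profile, simulate_dataset


def small_config(**overrides) -> SimulationConfig:
    """A fast, down-scaled simulation used by most unit tests."""
    kwargs = dict(
        n_genes=400,
        n_samples_per_group=5,
        n_exclusive_per_group=1,
        n_planted_triplets_per_group=1,
        seed=11,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def zero_noise_config(**overrides) -> SimulationConfig:
    """Degenerate-noise simulation: every present gene clears both cutoffs
    (intensity e^8 ~ 2981 >= 1000, SNR 10 >= 2) and absent genes never do."""
    kwargs = dict(intensity_log_sd=0.0, snr_log_sd=0.0)
    kwargs.update(overrides)
    return small_config(**kwargs)


@pytest.fixture(scope="session")
def study_scale():
    """One default-configuration (study-scale) dataset, simulated once."""
    config = SimulationConfig(seed=7)
    dataset, truth = simulate_dataset(config)
    profile = build_profile(dataset)
    return config, dataset, truth, profile


@pytest.fixture()
def small_sim():
    config = small_config()
    dataset, truth = simulate_dataset(config)
    return config, dataset, truth


@pytest.fixture()
def small_profile(small_sim):
    config, dataset, truth = small_sim
    return build_profile(dataset)


def random_detected(rng, n_genes=20, samples=("s1", "s2", "s3", "s4", "s5")) -> pd.DataFrame:
    """Random boolean detection matrix with no all-absent genes."""
    M = rng.random((n_genes, len(samples))) < 0.6
    M[~M.any(axis=1), 0] = True
    return pd.DataFrame(
        M, index=[f"g{i}" for i in range(n_genes)], columns=list(samples)
    )
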