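import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bcstgcn import (SimulationConfig, build_adjacency, build_pig_scheme,
                     normalize_coordinates, simulate_dataset)


@pytest.fixture(scope="session")
def scheme():
    return build_pig_scheme()


@pytest.fixture(scope="session")
def adj(scheme):
    return build_adjacency(scheme)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free synthetic clips: 5 per class, 50 frames."""
    cfg = SimulationConfig(n_per_class=5, T=50, noise_sigma=0.0,
                           occlusion_rate=0.0, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise synthetic clips: 5 per class, 50 frames."""
    cfg = SimulationConfig(n_per_class=5, T=50, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def normalized_batch(noisy_dataset):
    seqs = [normalize_coordinates(s) for s in noisy_dataset]
    X = np.stack([s.data for s in seqs])
    y = np.array([("feeding", "walking", "lying", "sitting").index(s.label)
                  for s in seqs])
    return X, y
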