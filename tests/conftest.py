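import numpy as np
import pytest

from fourc import (
    SimulationModel,
    correct_by_random_library,
    normalize,
    simulate_map,
    simulate_viewpoint,
)


@pytest.fixture(scope="session")
def small_model():
    """Compact locus so per-test simulation stays fast."""
    return SimulationModel(
        n_centromeric=40,
        n_cluster=30,
        n_telomeric=40,
        boundary=15,
        mean_fragment_length=300,
        min_fragment_length=100,
        depth=20_000,
        random_depth=100_000,
        hic_resolution=1500,
        hic_depth=500_000,
    )


@pytest.fixture(scope="session")
def small_map(small_model):
    fmap, _ = simulate_map(small_model, seed=1)
    return fmap


@pytest.fixture(scope="session")
def small_profile(small_model, small_map):
    raw, rnd, truth = simulate_viewpoint(small_model, small_map, seed=2)
    return normalize(correct_by_random_library(raw, rnd)), truth
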