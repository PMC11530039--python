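import numpy as np
import pytest

from gaitphase import (
    GaitSimConfig,
    build_window_pairs,
    fit_standardization,
    relative_positions,
    simulate_walk,
    standardize,
)


@pytest.fixture(scope="session")
def walk_small():
    """A short clean-ish walk: 8 s at 150 Hz, 1 stride/s, 0.5 mm marker noise."""
    return simulate_walk(GaitSimConfig(duration=8.0, cadence=1.0, noise_sd=0.5, seed=7))


@pytest.fixture(scope="session")
def pipeline_small(walk_small):
    """Standardization + window pairs for the left side of the small walk."""
    rel = relative_positions(walk_small.trajectory["left"])
    params = fit_standardization([rel])
    std = standardize(rel, params)
    batch = build_window_pairs(std, params)
    return {"rel": rel, "params": params, "std": std, "batch": batch}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
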