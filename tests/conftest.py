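import numpy as np
import pytest

from iftspread import default_seed_annotation, simulate_spreading_stack


@pytest.fixture(scope="session")
def small_phantom():
    """Down-scaled noisy phantom (2 cells, 96x96, 12 frames) for fast
    end-to-end tests; the full-size default phantom is exercised in the
    acceptance tests."""
    return simulate_spreading_stack(
        n_cells=2,
        n_frames=12,
        shape=(96, 96),
        a_max_range_um2=(120.0, 160.0),
        t0_range_s=(20.0, 30.0),
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom_seeds(small_phantom):
    return default_seed_annotation(small_phantom, rng_seed=42)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Piecewise-constant phantom: no shot/read noise, regular boundaries."""
    return simulate_spreading_stack(
        n_cells=2,
        n_frames=10,
        shape=(96, 96),
        a_max_range_um2=(120.0, 160.0),
        t0_range_s=(20.0, 30.0),
        gaussian_sigma=0.0,
        poisson=False,
        irregularity=0.0,
        rng_seed=3,
    )
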