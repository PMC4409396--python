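import numpy as np
import pandas as pd
import pytest

from palmquant import RunConfig, make_cell_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cell():
    """Default rod cell: 3 um long, 1 um wide."""
    return make_cell_geometry(3000.0, 500.0)


@pytest.fixture
def tiny_run_config():
    """A fast, small-but-complete simulated-cell configuration."""
    return RunConfig(
        seed=7,
        n_frames=2000,
        activation_prob=5e-3,
        n_clusters=3,
        emitters_per_cluster=40,
        n_background_emitters=20,
        background_rate_per_frame=0.01,
    )


def random_events(rng, n, n_frames=50, box=2000.0, max_photons=800.0):
    """A random localization-event table for property tests."""
    return pd.DataFrame(
        {
            "frame": rng.integers(0, n_frames, n),
            "x_nm": rng.uniform(0, box, n),
            "y_nm": rng.uniform(0, box, n),
            "photons": rng.uniform(1, max_photons, n),
        }
    )
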