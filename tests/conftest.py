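import numpy as np
import pytest

from silentnet import PopulationSpec, build_feedforward_weights, generate_raster


@pytest.fixture(scope="session")
def small_population():
    """A small mixed silent/active population raster with known weights."""
    spec = PopulationSpec(n_total=60, silent_fraction=0.5)
    raster = generate_raster(spec, n_trials=20, trial_duration=500.0, seed=7)
    weights = build_feedforward_weights(
        n_population=60, n_connected=30, n_excitatory=24, seed=7
    )
    return raster, weights


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
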