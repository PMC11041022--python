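import numpy as np
import pytest

from lamcsd import (
    GroupSpec,
    LayerMap,
    LfpRecording,
    SimConfig,
    StimulusSpec,
    default_sink_events,
    simulate_experiment,
)


@pytest.fixture
def small_config():
    """Two tiny groups, cheap geometry, deterministic seed."""
    return SimConfig(
        groups=(
            GroupSpec("treated", 2, 1.0, float(np.exp(-0.13))),
            GroupSpec("naive_control", 2),
        ),
        n_trials_per_condition=5,
        rng_seed=42,
    )


@pytest.fixture
def click5():
    return StimulusSpec.click_train(5)


@pytest.fixture
def small_dataset(small_config, click5):
    return simulate_experiment(small_config, [click5])


@pytest.fixture
def layer_map():
    return LayerMap.default_32()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(potentials, fs_hz=1000.0, spacing_um=50.0, **kw):
    return LfpRecording(np.asarray(potentials, dtype=float), fs_hz, spacing_um, **kw)


@pytest.fixture
def default_events():
    return default_sink_events()
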