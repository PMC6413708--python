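import numpy as np
import pytest

from gevikit.activation_segmentation import (
    activation_map,
    delta_f_sequence,
    preprocess_map_sequence,
)
from gevikit.dff_core import average_trials, pixel_bleach_fit
from gevikit.synthetic_scene import (
    simulate_trials,
    table1_config,
    table1_geometries,
    table1_protocol,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260917)


def _preset_run(kind: str, seed: int = 0):
    """Simulate a calibration-preset recording and run it to the map stage."""
    config = table1_config(seed=seed)
    geoms = table1_geometries(config)
    protocol = table1_protocol(kind, trial_count=4)
    movies, truth = simulate_trials(geoms, config, protocol, active=[True, False])
    avg = average_trials(movies)
    stim = protocol.stim_frames(config.frame_rate, config.n_frames)
    bleach = pixel_bleach_fit(avg, np.setdiff1d(np.arange(config.n_frames), stim))
    seq50, rate50 = preprocess_map_sequence(
        delta_f_sequence(avg, bleach), config.frame_rate, mode="visualization"
    )
    amap = activation_map(
        seq50, [protocol.stim_frames(rate50, seq50.shape[0])], config.pixel_size
    )
    return {
        "config": config,
        "geometries": geoms,
        "protocol": protocol,
        "movies": movies,
        "truth": truth,
        "avg": avg,
        "bleach": bleach,
        "amap": amap,
    }


@pytest.fixture(scope="session")
def map_run():
    """500 ms mapping-stimulus recording (anatomy-quality activation map)."""
    return _preset_run("map")


@pytest.fixture(scope="session")
def spikes_run():
    """Three-spike 20 Hz recording (single-AP signal sizes)."""
    return _preset_run("spikes")


@pytest.fixture(scope="session")
def depol_run():
    """100 ms depolarization recording (the summary-table stimulus)."""
    return _preset_run("depol")
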