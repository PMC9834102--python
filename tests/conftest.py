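import numpy as np
import pytest

from ioimap import (SimulationConfig, StimulusParadigm, compute_activity_map,
                    detrend_pixelwise, dice, segment_activation,
                    simulate_sequence)


@pytest.fixture
def small_config():
    """Fast, small-grid version of the default scenario."""
    return SimulationConfig(grid_rows=32, grid_cols=32, seed=0)


@pytest.fixture
def quiet_config():
    """No noise, no vasomotion, no drift: deterministic signal only."""
    return SimulationConfig(
        grid_rows=16,
        grid_cols=16,
        noise_sd=0.0,
        drift_slope=0.0,
        vasomotion_components=(),
        seed=0,
    )


@pytest.fixture
def short_paradigm():
    """2 cycles of 10 s + 10 s at 2 fps: 80 frames, f_stim = 0.05 Hz."""
    return StimulusParadigm(rest_duration=10, stim_duration=10,
                            cycles=2, frame_rate=2)


def recover_activation(seed: int, amplitude: float = -0.02,
                       grid: int = 128):
    """Full simulate -> detrend -> map -> segment chain for one seed.

    Returns the DICE between the recovered activation and the injected
    truth mask, plus the segmentation and truth for further checks.
    """
    config = SimulationConfig(
        grid_rows=grid, grid_cols=grid,
        activation_amplitude=amplitude, seed=seed,
    )
    seq, truth = simulate_sequence(config)
    amap = compute_activity_map(detrend_pixelwise(seq), config.paradigm)
    seg = segment_activation(amap, truth.trepanation_mask)
    return dice(seg.activation, truth.activation_mask), seg, truth


def random_mask(rng: np.random.Generator, shape=(24, 24), p=0.2) -> np.ndarray:
    return rng.random(shape) < p
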