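import logging

import numpy as np
import pytest

from barrelcross.agent import AgentConfig, BehavioralAgent
from barrelcross.engine import GapCrossConfig
from barrelcross.ois import StimulusProtocol
from barrelcross.phantom import OISPhantomConfig


@pytest.fixture(autouse=True)
def _quiet_stats_logging():
    """Listwise-drop warnings are expected in adaptive-sampling simulations."""
    logger = logging.getLogger("barrelcross.stats")
    level = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(level)


@pytest.fixture
def protocol() -> StimulusProtocol:
    return StimulusProtocol()


@pytest.fixture
def gc_config() -> GapCrossConfig:
    return GapCrossConfig()


@pytest.fixture
def small_phantom_config() -> OISPhantomConfig:
    """16x16, 200-frame (10-cycle) phantom for fast recovery checks."""
    return OISPhantomConfig(
        n_frames=200,
        frame_rate=1.0,
        stim_frequency=0.05,
        image_shape=(16, 16),
        blob_center=(8.0, 8.0),
        blob_sigma=2.0,
        peak_drr=1e-3,
        white_noise_sd=0.0,
        drift_amplitude=0.0,
        confound_frequencies=(),
        seed=0,
    )


@pytest.fixture
def deterministic_agent() -> BehavioralAgent:
    return BehavioralAgent(AgentConfig())


def brute_force_dft_bin(series: np.ndarray, k: int) -> complex:
    """Independent DFT oracle: explicit sum of x_t exp(-2 pi i k t / n)."""
    n = len(series)
    t = np.arange(n)
    return complex(np.sum(series * np.exp(-2j * np.pi * k * t / n)))
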