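from __future__ import annotations

import numpy as np
import pytest

from attneeg.channels import ALL_CHANNELS
from attneeg.config import EntropyParams, SimulationConfig
from attneeg.core import Epoch

#: Multiscale parameter sets over scales 1-10 (the index range), used where
#: a test works on short series.
SCALES_10 = {
    "mse": EntropyParams(m=2, r_factor=0.15, scales=tuple(range(1, 11))),
    "mfe": EntropyParams(m=2, r_factor=0.15, n=2.0, scales=tuple(range(1, 11))),
}


def small_sim_config(**overrides) -> SimulationConfig:
    """A light simulated session: quick to generate, full structure."""
    defaults = dict(
        n_subjects=2,
        n_trials=48,
        n_ax_trials=36,
        fs=160.0,
        rest_minutes=0.5,
        blink_rate=0.0,
        line_noise_amp=0.0,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture
def epoch_34ch(rng) -> Epoch:
    """A random 3-s epoch at 160 Hz with the full 34-channel layout."""
    return Epoch(
        data=rng.standard_normal((len(ALL_CHANNELS), 480)),
        fs=160.0,
        channel_labels=list(ALL_CHANNELS),
        subject_id="S00",
    )
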