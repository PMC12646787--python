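"""Shared fixtures: rendered eggs and synthetic clutch tables."""

import numpy as np
import pytest

from eggid.simulate import (
    ImageSynthConfig,
    SynthConfig,
    render_egg_image,
    synth_clutches,
)


@pytest.fixture(scope="session")
def spotted_egg():
    """A rendered egg with 12 well-separated uniform dark disks."""
    cfg = ImageSynthConfig(
        n_spots=12,
        spot_radius_mm=8 / 15.0,  # 8 px at 15 px/mm
        spot_radius_sd_mm=0.0,
        min_separation_mm=0.5,
        seed=42,
    )
    egg, truth = render_egg_image(cfg)
    return egg, truth, cfg


@pytest.fixture(scope="session")
def calibrated_clutches():
    """54 five-egg clutches at the study's within/between spreads."""
    clutches, table = synth_clutches(
        SynthConfig(n_females=54, eggs_per_clutch=5, seed=20)
    )
    return clutches, table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
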