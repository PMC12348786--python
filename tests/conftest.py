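import dataclasses

import numpy as np
import pytest

from canopycc import SimulationConfig, build_design, default_archetypes


@pytest.fixture
def green_archetype():
    return default_archetypes()["euonymus"]


@pytest.fixture
def quiet_green_archetype(green_archetype):
    """Green archetype with all per-pixel color jitter removed."""
    return dataclasses.replace(green_archetype, hue_sd=0.0)


@pytest.fixture
def tiny_design():
    return build_design(
        "tiny",
        species=("euonymus",),
        treatments=("full", "drought"),
        periods=("late",),
        replicates=2,
    )


@pytest.fixture
def noise_free_config(tiny_design):
    return SimulationConfig(
        design=tiny_design,
        image_size=(24, 24),
        pixel_noise_sd=0.0,
        illumination_jitter=0.0,
        background_fraction=0.3,
        season_start=(8, 1),
        season_end=(9, 30),
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
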