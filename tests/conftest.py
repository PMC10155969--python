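import numpy as np
import pytest

from emdlobula import (
    EMDConfig,
    NetworkConfig,
    OpticsConfig,
    StimulusSpec,
)


@pytest.fixture(scope="session")
def small_field_spec():
    """Reduced 60°x30° random-dot bar movie: fast enough for unit tests while
    keeping the full pipeline geometry (0.33°/px, eta=6, 2.6° dots)."""
    return StimulusSpec(
        kind="bar_on_ground",
        azimuth_extent=60.0,
        elevation_extent=30.0,
        figure_width=15.0,
        figure_height=30.0,
        figure_speed=66.0,
        background_speed=0.0,
        duration_frames=80,
        figure_start_deg=5.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_optics():
    return OpticsConfig()


@pytest.fixture
def default_emd():
    return EMDConfig()


@pytest.fixture
def default_network():
    return NetworkConfig()
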