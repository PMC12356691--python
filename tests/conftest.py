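import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epid2water import (
    BeamConfig,
    DetectorSpec,
    FieldSpec,
    GridSpec,
    WaterModel,
)

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_grid() -> GridSpec:
    """1 mm isocenter grid, +/-8 cm — enough for a 10x10 field with margins."""
    return GridSpec.at_isocenter(1.0, 80.0)


@pytest.fixture
def config_10x10() -> BeamConfig:
    return BeamConfig(field=FieldSpec.square(10.0), mu=100.0)


@pytest.fixture
def flat_config() -> BeamConfig:
    """Idealized beam: no horn, no penumbra, no extra-focal, no transmission."""
    return BeamConfig(
        field=FieldSpec.square(10.0),
        mu=100.0,
        horn_coeffs=(),
        source_sigma_mm=0.0,
        extrafocal_fraction=0.0,
        jaw_transmission=0.0,
    )


@pytest.fixture
def small_detector() -> DetectorSpec:
    """Response-free small panel for conservation/impulse checks."""
    return DetectorSpec(pixel_pitch_mm=1.0, n_pixels=161, offaxis_response_coeffs=())


@pytest.fixture
def water_model() -> WaterModel:
    return WaterModel()
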