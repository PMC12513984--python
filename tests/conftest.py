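import numpy as np
import pytest

from ccfd.synthetic import (
    GroundTruth,
    ShadowField,
    VesselNetworkParams,
    generate_cc_pattern,
)


@pytest.fixture(scope="session")
def default_truth():
    """One full-resolution capillary scene with a mid-range deficit target."""
    return generate_cc_pattern(VesselNetworkParams(target_fd_fraction=0.45, seed=11))


@pytest.fixture(scope="session")
def small_truth():
    """A cheap 512-px scene at the reference pixel pitch (1.5 mm extent)."""
    return generate_cc_pattern(
        VesselNetworkParams(target_fd_fraction=0.4, seed=7),
        fine_grid_px=512,
        extent_mm=1.5,
    )


@pytest.fixture()
def flat_field_truth():
    """Constant 0.5 flow field on a 400-px grid (no deficits)."""
    field = np.full((400, 400), 0.5)
    return GroundTruth(field, field == 0, 0.0, 7.5)


@pytest.fixture()
def no_shadow_512():
    return ShadowField.uniform(512)
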