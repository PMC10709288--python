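import numpy as np
import pytest

import dgecest as d

# study-condition constants shared by the dynamic recovery tests:
# volunteer dynamic scan length and the B0 drift reaching 0.05 ppm at its end
DYNAMIC_SCAN_S = 127 * 7.2
DRIFT_PPM_PER_S = 0.05 / DYNAMIC_SCAN_S
POST_SCAN_TIME_S = 180.0 + 780.0  # 13 min after infusion start


@pytest.fixture(scope="session")
def volunteer_schedule():
    return d.OffsetSchedule.volunteer_static()


@pytest.fixture(scope="session")
def wm_pools():
    """Direct-saturation + MT pools of the phantom's white matter."""
    truth = d.default_phantom(shape=(4, 4, 2))
    return truth.pool_params[1]


@pytest.fixture(scope="session")
def small_truth():
    """Noise-free default phantom on a reduced grid for fast tests."""
    return d.default_phantom(shape=(20, 20, 5))


def single_voxel_zvol(pools, offsets, b0_shift=0.0, extra_pools=()):
    """A 1-voxel ZSpectrumVolume built from the forward model."""
    z = d.zspectrum_forward(list(pools) + list(extra_pools), offsets,
                            b0_shift)
    return d.ZSpectrumVolume(z.reshape(1, 1, 1, -1), offsets,
                             np.ones((1, 1, 1)))
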