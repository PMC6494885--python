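import numpy as np
import pytest

from slicetrack.segment import Detection


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_detection(x, y, t=0.0, label=1, area=100.0, intensity=None):
    return Detection(
        timepoint_h=t,
        label=label,
        centroid_um=(float(x), float(y)),
        area_um2=area,
        mean_intensity=intensity or {"morphology": 100.0},
    )


@pytest.fixture
def small_movie_config():
    """A fast-to-render movie configuration used across tests."""
    from slicetrack.simulate import SimConfig

    return SimConfig(
        seed=7,
        n_cells=6,
        n_timepoints=8,
        image_shape=(3, 192, 192),
        voxel_size=(1.0, 1.0, 0.5),
        soma_radius_um=8.0,
        neurite_count=2,
        noise_sd_au=2.0,
    )
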