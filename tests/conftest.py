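"""Shared fixtures: small geometries, disk phantoms, tiny model configs."""

import numpy as np
import pytest

from fedct.geometry import ImageGrid, ScanGeometry
from fedct.models import ModelConfig


def make_disk(n_voxels: int, voxel_len: float, radius_frac: float = 0.35,
              value: float = 0.02) -> ImageGrid:
    """Uniform disk of attenuation ``value`` centred in the grid."""
    c = (np.arange(n_voxels) + 0.5 - n_voxels / 2.0) * voxel_len
    X, Y = np.meshgrid(c, c)
    r = radius_frac * n_voxels * voxel_len
    img = np.where(X ** 2 + Y ** 2 <= r ** 2, value, 0.0)
    return ImageGrid(img, voxel_len, "mu")


@pytest.fixture
def small_geom():
    return ScanGeometry(n_voxels=32, voxel_len=3.0, n_views=48, n_bins=47,
                        bin_len=3.0)


@pytest.fixture
def medium_geom():
    return ScanGeometry(n_voxels=64, voxel_len=3.0, n_views=180, n_bins=95,
                        bin_len=3.0)


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(sinogram_units=1, image_depth=2, shared_units=1,
                       base_channels=4, shared_channels=4, prompt_hidden=4,
                       groupnorm_groups=2, filtered_backprojection=True)
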