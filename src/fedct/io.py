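"""Config files and the array container format.

Geometries and protocols serialise to YAML blocks using the scan-protocol
vocabulary (``number_of_projection_views``, ``length_of_detector_bin_mm``,
``low_dose_protocol: {type, x_ray_intensity | sampling_views |
sampling_angle}`` ...).  Sinograms and images are stored as ``.npz``
containers with their geometry metadata attached; round-trips are lossless.
"""

from __future__ import annotations

import json

import numpy as np
import yaml

from .geometry import ImageGrid, ScanGeometry, Sinogram
from .lowdose import DoseProtocol


def save_config(path, cfg: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_sinogram(path, sino: Sinogram):
    np.savez(path, data=sino.data,
             geometry=json.dumps(sino.geometry.to_config()))


def load_sinogram(path) -> Sinogram:
    with np.load(path) as z:
        geom = ScanGeometry.from_config(json.loads(str(z["geometry"])))
        return Sinogram(z["data"], geom)


def save_image(path, img: ImageGrid):
    np.savez(path, data=img.data, voxel_len=img.voxel_len,
             value_unit=np.array(img.value_unit))


def load_image(path) -> ImageGrid:
    with np.load(path) as z:
        return ImageGrid(z["data"], float(z["voxel_len"]),
                         str(z["value_unit"]))


def protocol_to_config(proto: DoseProtocol) -> dict:
    return proto.to_config()


def protocol_from_config(cfg: dict) -> DoseProtocol:
    return DoseProtocol.from_config(cfg)
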