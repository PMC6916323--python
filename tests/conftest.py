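from __future__ import annotations

import numpy as np
import pytest

from fairomics.grid import BinaryMask, GridGeometry, ImageVolume
from fairomics.phantom import PhantomSpec, RoiSpec, SphereLesion, make_case

AXIAL = np.column_stack([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])


def volume_from_array(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    geom = GridGeometry(tuple(origin), tuple(spacing), AXIAL)
    return ImageVolume(voxels=np.asarray(arr, dtype=float), geometry=geom,
                       patient_id=kw.pop("patient_id", "T1"), **kw)


def full_mask(vol, name="all"):
    return BinaryMask(bits=np.ones(vol.shape, dtype=bool), roi_name=name, grid_ref=vol.geometry)


def mask_from_bits(vol, bits, name="roi"):
    return BinaryMask(bits=np.asarray(bits, dtype=bool), roi_name=name, grid_ref=vol.geometry)


@pytest.fixture(scope="session")
def sphere_case(tmp_path_factory):
    """One written-to-disk phantom case: sphere lesion + circle ROI around it."""
    spec = PhantomSpec(
        grid_shape=(12, 32, 32),
        spacing=(2.0, 1.0, 1.0),
        intensity_pattern=SphereLesion((16.0, 16.0, 10.0), 8.0, fg=100, bg=-50),
        rois=[
            RoiSpec("GTV-1", "circle", {"center_uv": (16.3, 16.2), "radius": 11.0,
                                        "n_vertices": 64}, (1, 9)),
            RoiSpec("ring", "ring", {"center_uv": (16.3, 16.2), "outer": 12.0, "inner": 5.0},
                    (3, 6)),
        ],
        patient_id="SPHERE-01",
    )
    return make_case(spec, tmp_path_factory.mktemp("sphere_case"))
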