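import numpy as np
import pytest

from rtdeface.geometry import GridGeometry
from rtdeface.phantom import PhantomSpec, generate_phantom
from rtdeface.pipeline import deface_case


def make_geometry(rows=8, cols=8, n_slices=4, spacing=(1.0, 1.0, 1.0),
                  origin=(0.0, 0.0, 0.0), frame="FOR-TEST"):
    dy, dx, dz = spacing
    return GridGeometry(
        origin=origin,
        pixel_spacing=(dy, dx),
        slice_positions=origin[2] + np.arange(n_slices) * dz,
        rows=rows,
        cols=cols,
        frame_of_reference_id=frame,
    )


@pytest.fixture(scope="session")
def phantom_below():
    return generate_phantom(PhantomSpec(ptv_mode="below"))


@pytest.fixture(scope="session")
def phantom_overlap():
    return generate_phantom(PhantomSpec(ptv_mode="overlap"))


@pytest.fixture(scope="session")
def phantom_same_slice():
    return generate_phantom(PhantomSpec(ptv_mode="same_slice"))


@pytest.fixture(scope="session")
def defaced_below(phantom_below):
    return deface_case(*phantom_below)


@pytest.fixture(scope="session")
def defaced_overlap(phantom_overlap):
    return deface_case(*phantom_overlap)
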