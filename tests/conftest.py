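import numpy as np
import pytest

from octanpa import BinaryMask, PhantomSpec, PipelineParams, generate_phantom

PS = 0.015  # mm/px of the reference device


@pytest.fixture
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A fast, small-field phantom spec shared by several tests."""
    return PhantomSpec(
        shape_px=(160, 224),
        n_large_vessels=1,
        n_ischemic_patches=1,
        patch_area_mm2_range=(0.12, 0.2),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


def make_mask(arr, pixel_size_mm=PS, role="vessel"):
    return BinaryMask(pixels=np.asarray(arr, dtype=np.uint8), pixel_size_mm=pixel_size_mm, role=role)
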