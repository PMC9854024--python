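import numpy as np
import pytest

from phonect import capture, phantom


@pytest.fixture(scope="session")
def study_geometry():
    return phantom.STUDY_GEOMETRY


@pytest.fixture(scope="session")
def menu():
    return phantom.default_lesion_menu()


@pytest.fixture(scope="session")
def ladder():
    return capture.default_device_ladder()


@pytest.fixture(scope="session")
def small_phantom(study_geometry):
    """An 8-slice, lesion-free stack for fast capture/frames tests."""
    geometry = phantom.StackGeometry(
        n_slices=8, rows=256, cols=256, mm_per_px=0.9, slice_thickness_mm=5.0
    )
    stack, truth = phantom.generate_phantom([], geometry=geometry, seed=42)
    return stack, truth


@pytest.fixture(scope="session")
def ellipsoid_stack():
    """One parenchymal ellipsoid (semi-axes 30, 20, 15 mm) on a fine grid."""
    geometry = phantom.StackGeometry(
        n_slices=60, rows=300, cols=300, mm_per_px=0.5, slice_thickness_mm=1.0
    )
    lesion = phantom.LesionSpec(
        kind="parenchymal",
        center_mm=(0.3, 0.7, 0.0),
        semi_axes_mm=(30.0, 20.0, 15.0),
    )
    stack, truth = phantom.generate_phantom(
        [lesion],
        geometry=geometry,
        noise_sd=0.0,
        seed=0,
        skull=(70.0, 72.0, 4.0),
    )
    mask = phantom.rasterize_lesion(lesion, geometry)
    return stack, truth, lesion, mask
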