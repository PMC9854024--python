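"""Measurement operators: ABC/2, subdural width, midline shift, CNR, Marshall."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonect import phantom, study
from phonect.metrics import (
    LesionROI,
    MetricError,
    abc2_volume,
    cnr,
    marshall_score,
    measure_abc,
    midline_shift,
    roi_from_masks,
    sdh_max_thickness,
    severity_class,
)
from phonect.phantom import LesionSpec, SliceStack, StackGeometry


def roi_for(stack, mask):
    return roi_from_masks(mask, study._brain_mask(stack))


class TestAbc2Volume:
    def test_zero_dimension_gives_zero(self):
        assert abc2_volume(0.0, 40.0, 30.0) == 0.0

    def test_hand_value(self):
        assert abc2_volume(60.0, 40.0, 30.0) == pytest.approx(36.0)

    def test_negative_rejected(self):
        with pytest.raises(MetricError):
            abc2_volume(-1.0, 2.0, 3.0)

    def test_ratio_to_exact_ellipsoid_volume(self, ellipsoid_stack):
        """ABC/2 overestimates the exact ellipsoid volume by 3/pi."""
        _, truth, _, _ = ellipsoid_stack
        assert truth.abc_volume_cc / truth.true_volume_cc == pytest.approx(
            3.0 / np.pi, rel=0.02
        )


class TestMeasureAbc:
    def test_recovers_generative_diameters(self, ellipsoid_stack):
        stack, _, lesion, mask = ellipsoid_stack
        a, b, c = measure_abc(stack, roi_for(stack, mask))
        vox = stack.geometry.mm_per_px
        assert a == pytest.approx(60.0, abs=vox)
        assert b == pytest.approx(40.0, abs=vox)
        assert abs(c - 30.0) <= stack.geometry.slice_thickness_mm

    def test_single_slice_lesion_c_is_thickness(self):
        geom = StackGeometry(n_slices=3, rows=64, cols=64, mm_per_px=1.0,
                             slice_thickness_mm=5.0)
        mask = np.zeros((3, 64, 64), dtype=bool)
        mask[1, 28:36, 24:40] = True
        brain = np.ones_like(mask)
        brain[:, :2] = False
        stack = SliceStack(geometry=geom,
                           pixels=np.full((3, 64, 64), 80.0, dtype=np.float32))
        _, _, c = measure_abc(stack, roi_from_masks(mask, brain))
        assert c == pytest.approx(5.0)

    def test_90_degree_rotation_swaps_a_and_b(self, ellipsoid_stack):
        stack, _, _, mask = ellipsoid_stack
        a, b, c = measure_abc(stack, roi_for(stack, mask))
        rot_pixels = np.rot90(stack.pixels, axes=(1, 2)).copy()
        rot_stack = SliceStack(geometry=stack.geometry, pixels=rot_pixels)
        rot_mask = np.rot90(mask, axes=(1, 2)).copy()
        a2, b2, c2 = measure_abc(rot_stack, roi_for(rot_stack, rot_mask))
        vox = stack.geometry.mm_per_px
        assert a2 == pytest.approx(a, abs=vox)
        assert b2 == pytest.approx(b, abs=vox)
        assert abc2_volume(a2, b2, c2) == pytest.approx(
            abc2_volume(a, b, c), rel=0.05
        )

    def test_empty_roi_rejected(self, ellipsoid_stack):
        stack, _, _, mask = ellipsoid_stack
        with pytest.raises(MetricError):
            measure_abc(stack, roi_for(stack, np.zeros_like(mask)))


@pytest.fixture(scope="module")
def crescent_stack():
    geom = StackGeometry(n_slices=8, rows=256, cols=256, mm_per_px=0.9,
                         slice_thickness_mm=5.0)
    lesion = LesionSpec(kind="subdural", center_mm=(0, 0, 0),
                        semi_axes_mm=(55.0, 3.85, 10.0))
    stack, _ = phantom.generate_phantom([lesion], geometry=geom, seed=2)
    mask = phantom.rasterize_lesion(lesion, geom)
    return stack, mask


class TestSdhThickness:
    def test_recovers_generative_width(self, crescent_stack):
        stack, mask = crescent_stack
        width, low_conf = sdh_max_thickness(stack, roi_for(stack, mask))
        assert width == pytest.approx(7.7, abs=2 * stack.geometry.mm_per_px)
        assert not low_conf

    def test_pristine_equals_identity_captured(self, crescent_stack):
        from phonect import capture, frames

        stack, mask = crescent_stack
        result = capture.simulate_capture(stack, capture.IDENTITY_PROFILE, seed=0)
        rec = frames.deduplicate_slices(result.frames, slice_thickness_mm=5.0)
        rec = SliceStack(
            geometry=rec.geometry.with_scale(stack.geometry.mm_per_px),
            pixels=rec.pixels,
        )
        w1, _ = sdh_max_thickness(stack, roi_for(stack, mask))
        w2, _ = sdh_max_thickness(rec, roi_for(rec, mask))
        assert w1 == w2

    def test_subpixel_width_flagged_low_confidence(self):
        geom = StackGeometry(n_slices=1, rows=64, cols=64, mm_per_px=1.0,
                             slice_thickness_mm=5.0)
        mask = np.zeros((1, 64, 64), dtype=bool)
        mask[0, 30, 10:40] = True  # 1 px thin line
        brain = np.ones_like(mask)
        pixels = np.full((1, 64, 64), 80.0, dtype=np.float32)
        pixels[0][mask[0]] = 160.0
        stack = SliceStack(geometry=geom, pixels=pixels)
        _, low_conf = sdh_max_thickness(stack, roi_from_masks(mask, brain))
        assert low_conf

    def test_empty_roi_rejected(self, crescent_stack):
        stack, mask = crescent_stack
        with pytest.raises(MetricError):
            sdh_max_thickness(stack, roi_for(stack, np.zeros_like(mask)))


class TestMidlineShift:
    GEOM = phantom.STUDY_GEOMETRY

    def test_symmetric_phantom_measures_zero(self):
        stack, _ = phantom.generate_phantom([], geometry=self.GEOM,
                                            shift_mm=0.0, seed=5)
        assert midline_shift(stack) <= self.GEOM.mm_per_px

    def test_recovers_large_generative_shift(self):
        stack, _ = phantom.generate_phantom([], geometry=self.GEOM,
                                            shift_mm=27.0, seed=5)
        assert midline_shift(stack) == pytest.approx(
            27.0, abs=2 * self.GEOM.mm_per_px
        )

    def test_mirrored_stack_same_magnitude(self):
        stack, _ = phantom.generate_phantom([], geometry=self.GEOM,
                                            shift_mm=10.0, seed=5)
        mirrored = SliceStack(
            geometry=stack.geometry, pixels=stack.pixels[:, :, ::-1].copy()
        )
        assert midline_shift(mirrored) == pytest.approx(
            midline_shift(stack), abs=self.GEOM.mm_per_px
        )

    def test_undetectable_structure_errors(self):
        geom = StackGeometry(n_slices=2, rows=64, cols=64, mm_per_px=1.0,
                             slice_thickness_mm=5.0)
        stack = SliceStack(
            geometry=geom, pixels=np.full((2, 64, 64), 80.0, dtype=np.float32)
        )
        with pytest.raises(MetricError):
            midline_shift(stack)


def _two_region_stack(lesion_values, surround_values):
    """1-slice stack with given lesion / surround pixel values."""
    n_l, n_s = len(lesion_values), len(surround_values)
    cols = n_l + n_s
    pixels = np.array([list(lesion_values) + list(surround_values)],
                      dtype=np.float64).reshape(1, 1, cols)
    pixels = np.repeat(pixels, 3, axis=1)  # avoid degenerate 1-row shapes
    pixels = pixels.astype(np.float32)
    lesion = np.zeros((1, 3, cols), dtype=bool)
    lesion[:, :, :n_l] = True
    surround = np.zeros_like(lesion)
    surround[:, :, n_l:] = True
    geom = StackGeometry(n_slices=1, rows=3, cols=cols, mm_per_px=1.0,
                         slice_thickness_mm=5.0)
    return SliceStack(geometry=geom, pixels=pixels), LesionROI(lesion, surround)


class TestCnr:
    def test_equal_means_give_zero(self):
        stack, roi = _two_region_stack([80.0] * 4, [70.0, 90.0, 75.0, 85.0])
        assert cnr(stack, roi) == 0.0

    def test_monte_carlo_value(self):
        rng = np.random.default_rng(0)
        surround = rng.normal(80.0, 16.0, size=4000)
        stack, roi = _two_region_stack([160.0] * 50, surround)
        assert cnr(stack, roi) == pytest.approx(5.0, rel=0.05)

    def test_zero_surround_variance_errors(self):
        stack, roi = _two_region_stack([160.0] * 4, [80.0] * 4)
        with pytest.raises(MetricError, match="undefined"):
            cnr(stack, roi)

    @settings(deadline=None, max_examples=50)
    @given(
        gain=st.floats(min_value=0.05, max_value=5.0),
        offset=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_affine_luminance_invariance(self, gain, offset):
        """CNR is exactly invariant under I -> g*I + o with g > 0."""
        rng = np.random.default_rng(7)
        surround = rng.normal(80.0, 10.0, size=200)
        stack, roi = _two_region_stack([160.0] * 20, surround)
        base = cnr(stack, roi)
        transformed = SliceStack(
            geometry=stack.geometry,
            pixels=(gain * stack.pixels + offset).astype(np.float32),
        )
        assert cnr(transformed, roi) == pytest.approx(base, rel=1e-4)


def marshall_oracle(mass_cc, shift_mm, cisterns_effaced, evacuated, visible):
    """Independent rubric oracle: collect all matching categories, then
    resolve by the documented precedence 6/5 > 4 > 3 > 2 > 1."""
    matches = {1}
    if visible:
        matches.add(2)
    if cisterns_effaced:
        matches.add(3)
    if shift_mm > 5:
        matches.add(4)
    if mass_cc > 25 and evacuated:
        matches.add(5)
    if mass_cc > 25 and not evacuated:
        matches.add(6)
    for category in (6, 5, 4, 3, 2, 1):
        if category in matches:
            return category


class TestMarshall:
    def test_matches_exhaustive_oracle(self):
        for mass in (0.0, 3.5, 24.9, 25.0, 25.1, 190.41):
            for shift in (0.0, 4.9, 5.0, 5.1, 27.11):
                for cist in (False, True):
                    for evac in (False, True):
                        for vis in (False, True):
                            assert marshall_score(mass, shift, cist, evac, vis) == \
                                marshall_oracle(mass, shift, cist, evac, vis), \
                                (mass, shift, cist, evac, vis)

    def test_negative_inputs_rejected(self):
        with pytest.raises(MetricError):
            marshall_score(-1.0, 0.0, False, False, False)
        with pytest.raises(MetricError):
            marshall_score(0.0, -2.0, False, False, False)


class TestSeverityClass:
    @pytest.mark.parametrize(
        "kind,kwargs,expected",
        [
            ("subdural", {"width_mm": 12.4}, "severe"),
            ("subdural", {"width_mm": 5.0}, "moderate"),
            ("subdural", {"width_mm": 4.9}, "mild"),
            ("parenchymal", {"total_volume_cc": 35.0}, "severe"),
            ("multi-compartment", {"total_volume_cc": 10.0}, "moderate"),
            ("multi-compartment", {"total_volume_cc": 3.0}, "mild"),
        ],
    )
    def test_bins(self, kind, kwargs, expected):
        assert severity_class(kind, **kwargs) == expected

    def test_unknown_kind_rejected(self):
        with pytest.raises(MetricError):
            severity_class("epidural", width_mm=3.0)
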