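"""Rotated-rectangle morphometry: fitting, orientation, upright rotation."""

import math

import numpy as np
import pytest

from seggrade.errors import DegenerateGeometryError, EmptyClassError
from seggrade.fixtures import FixtureSpec, render_mushroom
from seggrade.mask import CAP, STALK, LabelMask
from seggrade.morphometry import (
    AmbiguousOrientationWarning,
    CapMeasurement,
    RotatedRect,
    StalkMeasurement,
    compute_ratios,
    extract_component_mask,
    measure_cap,
    measure_mushroom,
    measure_stalk,
    min_bounding_rect,
    normalize_angle,
    rotate_upright,
)

from conftest import calipers_min_area, foreground_centers, pixel_corner_cloud


def block_mask(h: int, w: int, value: int = 1, pad: int = 4) -> LabelMask:
    arr = np.zeros((h + 2 * pad, w + 2 * pad), dtype=np.uint8)
    arr[pad : pad + h, pad : pad + w] = value
    return LabelMask(arr)


class TestExtractComponent:
    def test_single_block_counts(self):
        mask = block_mask(20, 40, value=CAP)
        comp = extract_component_mask(mask, CAP)
        assert comp.pixel_count == 800
        assert comp.component_count == 1
        assert comp.mask.labels.sum() == 800

    def test_largest_of_two_blobs_retained(self):
        arr = np.zeros((40, 80), dtype=np.uint8)
        arr[5:25, 5:45] = CAP      # 800 px
        arr[30:35, 60:70] = CAP    # 50 px
        comp = extract_component_mask(LabelMask(arr), CAP)
        assert comp.component_count == 2
        assert comp.mask.labels.sum() == 800
        assert comp.pixel_count == 850

    def test_empty_class_raises(self):
        mask = LabelMask(np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(EmptyClassError):
            extract_component_mask(mask, STALK)


class TestMinBoundingRect:
    def test_axis_aligned_block(self):
        rect = min_bounding_rect(block_mask(20, 40))
        assert rect.long_side == pytest.approx(40, abs=1)
        assert rect.short_side == pytest.approx(20, abs=1)
        assert rect.angle_deg == pytest.approx(0, abs=1)

    def test_rotated_block_recovers_angle_and_sides(self):
        # rasterize a 40x20 rectangle at 30 degrees analytically
        yy, xx = np.mgrid[0:100, 0:100].astype(float)
        th = math.radians(30)
        lx = math.cos(th) * (xx - 50) + math.sin(th) * (yy - 50)
        ly = -math.sin(th) * (xx - 50) + math.cos(th) * (yy - 50)
        arr = ((np.abs(lx) <= 20) & (np.abs(ly) <= 10)).astype(np.uint8)
        rect = min_bounding_rect(LabelMask(arr))
        assert rect.long_side == pytest.approx(40, abs=2)
        assert rect.short_side == pytest.approx(20, abs=2)
        assert rect.angle_deg == pytest.approx(30, abs=2)

    @pytest.mark.parametrize(
        "arr",
        [
            np.zeros((10, 10), dtype=np.uint8),
            np.eye(10, dtype=np.uint8),                       # 1-px diagonal line
            np.pad(np.ones((1, 1), np.uint8), 4),             # single pixel
        ],
        ids=["empty", "diagonal-line", "single-pixel"],
    )
    def test_degenerate_masks_raise(self, arr):
        with pytest.raises(DegenerateGeometryError):
            min_bounding_rect(LabelMask(arr))

    def test_minimality_vs_axis_aligned_box(self, random_convex_blob):
        rng = np.random.default_rng(11)
        for _ in range(25):
            blob = random_convex_blob(rng)
            rect = min_bounding_rect(LabelMask(blob.astype(np.uint8)))
            corners = pixel_corner_cloud(blob)
            aabb = (corners[:, 0].max() - corners[:, 0].min()) * (
                corners[:, 1].max() - corners[:, 1].min()
            )
            assert rect.area <= aabb * (1 + 1e-9)

    def test_matches_rotating_calipers_oracle(self, random_convex_blob):
        rng = np.random.default_rng(5)
        for _ in range(20):
            blob = random_convex_blob(rng)
            rect = min_bounding_rect(LabelMask(blob.astype(np.uint8)))
            oracle = calipers_min_area(foreground_centers(blob), inflation=1.0)
            assert rect.area == pytest.approx(oracle, rel=0.01)


class TestMeasureCap:
    @pytest.mark.parametrize("angle,expected_tilt", [(0, 0), (25, 25), (-40, -40)])
    def test_d1_h_and_tilt(self, angle, expected_tilt):
        rect = RotatedRect(50, 50, 60, 30, angle)
        cap = measure_cap(rect)
        assert cap.D1 == 60 and cap.H == 30
        assert cap.tilt_deg == pytest.approx(expected_tilt)

    def test_near_square_cap_warns_but_returns(self):
        rect = RotatedRect(50, 50, 40, 39.5, 10)
        with pytest.warns(AmbiguousOrientationWarning):
            cap = measure_cap(rect, tie_tolerance=1.0)
        assert cap.D1 == 40 and cap.H == 39.5


class TestRotateUpright:
    def test_zero_tilt_is_identity(self):
        mask = block_mask(20, 40)
        assert rotate_upright(mask, 0.0) == mask

    def test_roundtrip_angle_near_zero(self):
        yy, xx = np.mgrid[0:100, 0:100].astype(float)
        th = math.radians(30)
        lx = math.cos(th) * (xx - 50) + math.sin(th) * (yy - 50)
        ly = -math.sin(th) * (xx - 50) + math.cos(th) * (yy - 50)
        arr = ((np.abs(lx) <= 20) & (np.abs(ly) <= 10)).astype(np.uint8)
        rect = min_bounding_rect(LabelMask(arr))
        upright = rotate_upright(LabelMask(arr), rect.angle_deg)
        rect2 = min_bounding_rect(upright)
        assert rect2.angle_deg == pytest.approx(0, abs=2)

    @pytest.mark.parametrize("tilt", [17.0, 45.0, 78.0, -33.0])
    def test_foreground_count_conserved(self, tilt):
        spec = FixtureSpec(D1=50, H=26, L=40, D2=16)
        mask = render_mushroom(spec).mask
        before = int(np.count_nonzero(mask.labels))
        after = int(np.count_nonzero(rotate_upright(mask, tilt).labels))
        assert after == pytest.approx(before, rel=0.05)

    def test_labels_preserved_categorical(self):
        mask = render_mushroom(FixtureSpec(D1=50, H=26, L=40, D2=16)).mask
        rotated = rotate_upright(mask, 30.0)
        assert set(np.unique(rotated.labels)) <= {0, CAP, STALK}


class TestMeasureStalk:
    def test_near_vertical_long_side_is_length(self):
        rect = RotatedRect(0, 0, 80, 20, 88)  # long side 88 deg from x-axis
        s = measure_stalk(rect)
        assert s.L == 80 and s.D2 == 20

    def test_horizontal_long_side_vertical_rule_governs(self):
        rect = RotatedRect(0, 0, 80, 20, 0)  # squat, tilted stalk
        s = measure_stalk(rect)
        assert s.L == 20 and s.D2 == 80

    def test_45_degree_tie_resolves_to_long_side(self):
        rect = RotatedRect(0, 0, 80, 20, 45)
        with pytest.warns(AmbiguousOrientationWarning):
            s = measure_stalk(rect)
        assert s.L == 80 and s.D2 == 20


class TestRatios:
    def test_reference_values(self):
        m = compute_ratios(
            CapMeasurement(D1=60, H=30, tilt_deg=0), StalkMeasurement(L=40, D2=20)
        )
        assert m.RDHP == pytest.approx(2.0)
        assert m.RLDS == pytest.approx(2.0)

    def test_square_cap_unit_ratio(self):
        m = compute_ratios(
            CapMeasurement(D1=40, H=40, tilt_deg=0), StalkMeasurement(L=10, D2=20)
        )
        assert m.RDHP == 1.0
        assert m.RLDS == 0.5


class TestInvariants:
    @pytest.mark.parametrize("theta", list(range(0, 360, 15)))
    def test_rotation_invariance(self, theta):
        spec = FixtureSpec(D1=60, H=30, L=40, D2=20, rotation_deg=float(theta))
        out = measure_mushroom(render_mushroom(spec).mask)
        m = out.measurement
        assert m.cap.D1 == pytest.approx(spec.D1, abs=3)
        assert m.cap.H == pytest.approx(spec.H, abs=3)
        assert m.stalk.L == pytest.approx(spec.L, abs=3)
        assert m.stalk.D2 == pytest.approx(spec.D2, abs=3)
        assert m.RDHP == pytest.approx(spec.true_RDHP, rel=0.05)
        assert m.RLDS == pytest.approx(spec.true_RLDS, rel=0.05)

    def test_scale_equivariance(self):
        small = FixtureSpec(D1=50, H=26, L=36, D2=16, rotation_deg=20)
        big = FixtureSpec(D1=100, H=52, L=72, D2=32, rotation_deg=20)
        ms = measure_mushroom(render_mushroom(small).mask).measurement
        mb = measure_mushroom(render_mushroom(big).mask).measurement
        for attr_s, attr_b in (
            (ms.cap.D1, mb.cap.D1), (ms.cap.H, mb.cap.H),
            (ms.stalk.L, mb.stalk.L), (ms.stalk.D2, mb.stalk.D2),
        ):
            assert attr_b == pytest.approx(2 * attr_s, abs=2)
        assert mb.RDHP == pytest.approx(ms.RDHP, rel=0.02)
        assert mb.RLDS == pytest.approx(ms.RLDS, rel=0.02)


def test_normalize_angle_folds_into_half_open_range():
    assert normalize_angle(90) == -90
    assert normalize_angle(-90) == -90
    assert normalize_angle(135) == -45
    assert normalize_angle(30) == 30
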