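"""Alignment and trait measurement against analytic/generator ground truth."""

import numpy as np
import pandas as pd
import pytest
from skimage.transform import rotate

from conftest import make_disc
from fruitmorph.morphology import (
    MeasurementError,
    align,
    correlation_matrix,
    derived_traits,
    measure_almond,
    measure_general,
    TraitRecord,
)
from fruitmorph.preprocess import PixelScale
from fruitmorph.synthetic import SeedShapeParams, generate_shape

SCALE = PixelScale(6.0, "manual")


def measure_mask(mask, scale=SCALE):
    aligned = align(mask)
    rec = measure_general(aligned, scale)
    measure_almond(aligned, scale, record=rec)
    return rec


class TestAlign:
    def test_vertical_ellipse_unrotated_unflipped(self, ellipse_shape):
        aligned = align(ellipse_shape.mask)
        assert abs(aligned.rotation_deg) < 1.0
        assert not aligned.flipped_v

    def test_rotated_ellipse_brought_back_vertical(self, ellipse_shape):
        rotated = rotate(ellipse_shape.mask.astype(float), 30, resize=True, order=0) > 0.5
        aligned = align(rotated)
        from skimage.measure import regionprops

        residual = np.degrees(regionprops(aligned.mask.astype(np.uint8))[0].orientation)
        assert abs(residual) < 1.0
        assert aligned.rotation_deg == pytest.approx(-30, abs=1.5)

    def test_teardrop_tip_up_right_gets_both_flips(self):
        # sharp pole up, skew putting the tip right of the centroid
        shape = generate_shape(
            SeedShapeParams(26, 13, 0.9, shoulder_asym=-0.4, lateral_asym=0.1), 6.0
        )
        flipped = rotate(shape.mask[::-1, ::-1].astype(float), 0, order=0) > 0.5
        aligned = align(flipped)
        tip_row, tip_col = aligned.tip
        assert tip_row > aligned.centroid[0]  # tip in lower half
        assert tip_col <= aligned.centroid[1] + 1  # tip not right of centroid

    def test_degenerate_contour_rejected(self):
        tiny = np.zeros((10, 10), bool)
        tiny[5, 5] = True
        with pytest.raises(MeasurementError):
            align(tiny)


class TestMeasureGeneral:
    def test_disc_traits_analytic(self):
        mask = make_disc(100)
        rec = measure_mask(mask, PixelScale(4.0, "manual"))
        assert rec.length == pytest.approx(50.0, rel=0.02)
        assert rec.width == pytest.approx(50.0, rel=0.02)
        assert rec.circularity >= 0.98
        assert rec.solidity >= 0.99
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.02)
        assert rec.ellipse_ratio == pytest.approx(1.0, abs=0.02)

    def test_rectangle_aspect_ratio(self):
        mask = np.zeros((240, 140), bool)
        mask[20:220, 20:120] = True  # 200 x 100 px
        rec = measure_mask(mask)
        assert rec.aspect_ratio == pytest.approx(2.0, rel=0.02)
        assert rec.solidity == pytest.approx(1.0, abs=0.01)

    def test_generator_oracle_geometry(self, random_shapes):
        """Lengths/widths within 2%, area within 1% of analytic truth."""
        for shape in random_shapes:
            rec = measure_mask(shape.mask)
            truth = shape.truth
            assert rec.length == pytest.approx(truth["length"], rel=0.02)
            assert rec.width == pytest.approx(truth["width"], rel=0.02)
            assert rec.area == pytest.approx(truth["area"], rel=0.01)
            assert rec.perimeter == pytest.approx(truth["perimeter"], rel=0.02)
            for q in (25, 50, 75):
                assert getattr(rec, f"width_at_{q}") == pytest.approx(
                    truth[f"width_at_{q}"], rel=0.02
                ), f"width_at_{q}"

    def test_trait_record_invariants_on_batch(self, random_shapes):
        for shape in random_shapes:
            rec = measure_mask(shape.mask)
            assert 0 < rec.solidity <= 1
            assert rec.aspect_ratio >= 1
            assert 0 < rec.circularity <= 1.02
            assert rec.area <= rec.hull_area
            for name in ("sym_vertical", "sym_horizontal", "sym_shoulder"):
                assert 0 <= getattr(rec, name) <= 1
            two_px_mm = 2 / 6.0
            for q in (25, 50, 75):
                assert getattr(rec, f"width_at_{q}") <= rec.width + two_px_mm

    def test_color_means_from_uniform_pixels(self, ellipse_shape):
        aligned = align(ellipse_shape.mask)
        pixels = np.tile(np.array([[200, 120, 60]], dtype=np.uint8), (50, 1))
        rec = measure_general(aligned, SCALE, rgb_pixels=pixels)
        from skimage.color import rgb2lab

        expected = rgb2lab(np.array([[[200 / 255, 120 / 255, 60 / 255]]]))[0, 0]
        assert rec.color_L == pytest.approx(expected[0], abs=0.01)
        assert rec.color_a == pytest.approx(expected[1], abs=0.01)
        assert rec.color_b == pytest.approx(expected[2], abs=0.01)

    def test_rotation_invariance_of_traits(self, ellipse_shape):
        base = measure_mask(ellipse_shape.mask)
        for angle in (17, 63, 111):
            rot = rotate(ellipse_shape.mask.astype(float), angle, resize=True, order=0) > 0.5
            rec = measure_mask(rot)
            assert rec.length == pytest.approx(base.length, rel=0.02)
            assert rec.width == pytest.approx(base.width, rel=0.02)
            assert rec.area == pytest.approx(base.area, rel=0.02)
            assert rec.circularity == pytest.approx(base.circularity, rel=0.02)

    def test_scale_covariance(self, ellipse_shape):
        rec4 = measure_mask(ellipse_shape.mask, PixelScale(4.0, "manual"))
        rec8 = measure_mask(ellipse_shape.mask, PixelScale(8.0, "manual"))
        assert rec8.length == pytest.approx(rec4.length / 2, rel=1e-9)
        assert rec8.area == pytest.approx(rec4.area / 4, rel=1e-9)
        assert rec8.circularity == pytest.approx(rec4.circularity, rel=0.01)
        assert rec8.solidity == pytest.approx(rec4.solidity, rel=0.01)

    def test_circularity_of_discs_grows_toward_one(self):
        values = []
        for r in (20, 35, 50, 75, 100, 140, 200):
            circs = [
                measure_mask(make_disc(r, offset=off)).circularity
                for off in ((0.0, 0.0), (0.25, 0.4), (0.5, 0.5), (0.13, 0.77))
            ]
            values.append(np.mean(circs))
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] >= 0.98


class TestMeasureAlmond:
    def test_symmetric_ellipse_fully_symmetric(self, ellipse_shape):
        rec = measure_mask(ellipse_shape.mask)
        assert rec.sym_vertical == pytest.approx(1.0, abs=0.01)
        assert rec.sym_horizontal == pytest.approx(1.0, abs=0.01)
        assert rec.sym_shoulder == pytest.approx(1.0, abs=0.01)
        assert rec.width_at_50 == pytest.approx(rec.width, rel=0.02)

    def test_dilating_one_side_lowers_vertical_symmetry(self, ellipse_shape):
        mask = ellipse_shape.mask
        base = measure_mask(mask).sym_vertical
        # stretch the left half horizontally by 10%
        h, w = mask.shape
        cols = np.arange(w)
        rows_idx, cols_idx = np.nonzero(mask)
        center = cols_idx.mean()
        warped = np.zeros_like(mask)
        for r, c in zip(rows_idx, cols_idx):
            if c < center:
                c = int(round(center + (c - center) * 1.1))
            if 0 <= c < w:
                warped[r, c] = True
        from scipy import ndimage as ndi

        warped = ndi.binary_closing(warped)
        asym = measure_mask(warped).sym_vertical
        assert asym < 1.0
        assert asym < base

    def test_lateral_asymmetry_monotone(self):
        syms = []
        for lat in (0.0, 0.05, 0.12):
            shape = generate_shape(SeedShapeParams(26, 14, 0.85, 0.0, lat), 6.0)
            syms.append(measure_mask(shape.mask).sym_vertical)
        assert syms[0] > syms[1] > syms[2]


class TestDerivedTraits:
    def test_weight_ratio_and_globosity_arithmetic(self):
        rec = TraitRecord(width=12.0)
        derived_traits(rec, kernel_weight=1.2, shell_weight=4.8)
        assert rec.weight_ratio_kernel_shell == pytest.approx(0.25)

        class FlatModel:
            def predict(self, area, weight):
                return np.full(len(np.atleast_1d(area)), 8.0)

        rec2 = TraitRecord(width=12.0, area=200.0)
        derived_traits(rec2, kernel_weight=1.2, thickness_model=FlatModel())
        assert rec2.thickness_est == pytest.approx(8.0)
        assert rec2.globosity == pytest.approx(1.5)

    def test_missing_weights_leave_fields_unset(self):
        rec = TraitRecord(width=12.0, area=200.0)
        derived_traits(rec)
        assert rec.weight is None and rec.weight_ratio_kernel_shell is None

    def test_zero_shell_weight_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            derived_traits(TraitRecord(), kernel_weight=1.0, shell_weight=0.0)


class TestCorrelationMatrix:
    def test_self_and_negated_columns(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": -x})
        corr, count = correlation_matrix(df, threshold=0.75)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert count == 3  # all three pairs perfectly correlated

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("abcd"))
        corr, count = correlation_matrix(df, threshold=0.75)
        off = corr.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert count == 0

    def test_constant_column_reported_missing(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
        corr, _ = correlation_matrix(df)
        assert np.isnan(corr.loc["a", "b"])
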