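"""Volume pipeline: resampling, alignment, rasterization, crop, normalize."""

import numpy as np
import pytest

from jeps.volume import (MultiChannelVolume, StructureSet, VoxelGrid,
                         align_dose_to_ct, assemble_channels, crop_volume,
                         dose_normalize, hu_window_normalize,
                         parotid_axial_center, rasterize_structure,
                         resample_to_spacing, sagittal_mirror)


def grid(values, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return VoxelGrid(np.asarray(values, dtype=float), spacing, origin)


class TestResample:
    def test_identity_at_same_spacing(self, rng):
        g = grid(rng.normal(size=(6, 7, 8)), spacing=(2, 2, 2))
        out = resample_to_spacing(g, (2, 2, 2))
        assert np.allclose(out.values, g.values, atol=1e-6)

    def test_constant_field_stays_constant(self):
        g = grid(np.full((5, 5, 5), 3.7), spacing=(1, 2, 3))
        out = resample_to_spacing(g, (0.5, 1.0, 1.5))
        assert np.allclose(out.values, 3.7)

    def test_linear_ramp_downsampled_exactly(self):
        # cubic splines reproduce polynomials of degree <= 3
        z = np.arange(20)[:, None, None] * 1.0
        g = grid(np.broadcast_to(z, (20, 8, 8)).copy(), spacing=(1, 1, 1))
        out = resample_to_spacing(g, (2, 1, 1))
        expected = np.arange(out.shape[0])[:, None, None] * 2.0
        assert np.abs(out.values - expected).max() < 1e-3 * 19

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample_to_spacing(grid(np.ones((4, 4, 4))), (0, 1, 1))


class TestAlignDose:
    def test_identity_when_lattices_match(self, rng):
        d = grid(rng.random((6, 6, 6)))
        ct = grid(np.zeros((6, 6, 6)))
        out = align_dose_to_ct(d, ct)
        assert np.allclose(out.values, d.values, atol=1e-9)

    def test_whole_voxel_translation_shifts_values(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 1.0
        d = VoxelGrid(vals, (1, 1, 1), origin_mm=(1.0, 0.0, 0.0))
        ct = grid(np.zeros((5, 5, 5)))
        out = align_dose_to_ct(d, ct)
        assert out.values[3, 2, 2] == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_extents_error(self):
        d = VoxelGrid(np.ones((3, 3, 3)), (1, 1, 1), origin_mm=(100, 100, 100))
        ct = grid(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            align_dose_to_ct(d, ct)


def _ray_cast_inside(poly, x, y):
    """Independent point-in-polygon oracle (crossing number + boundary check)."""
    n = len(poly)
    on_edge = False
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-9 and min(x1, x2) - 1e-9 <= x <= max(x1, x2) + 1e-9 \
                and min(y1, y2) - 1e-9 <= y <= max(y1, y2) + 1e-9:
            on_edge = True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside or on_edge


class TestRasterize:
    def test_axis_aligned_rectangle_fills_expected_voxels(self):
        ct = grid(np.zeros((3, 10, 10)))
        # rectangle spanning x 2..7 and y 3..6 -> 6 x 4 = 24 voxel centers
        poly = np.array([[2, 3], [7, 3], [7, 6], [2, 6]], dtype=float)
        ss = StructureSet({"PTV": [(1.0, poly)]})
        mask = rasterize_structure(ss, "PTV", ct)
        assert mask.values[1].sum() == 24
        assert mask.values[0].sum() == 0

    def test_between_slice_contour_maps_to_nearest(self):
        ct = grid(np.zeros((4, 6, 6)), spacing=(2, 1, 1))
        poly = np.array([[1, 1], [4, 1], [4, 4], [1, 4]], dtype=float)
        ss = StructureSet({"PTV": [(2.9, poly)]})     # between z=2 and z=4
        mask = rasterize_structure(ss, "PTV", ct)
        assert mask.values[1].sum() > 0               # nearest slice is z=2
        assert mask.values[2].sum() == 0

    def test_missing_roi_lists_available(self):
        ss = StructureSet({"PTV": [(0.0, np.zeros((3, 2)))]})
        ct = grid(np.zeros((2, 4, 4)))
        with pytest.raises(KeyError, match="PTV"):
            rasterize_structure(ss, "Nope", ct)

    def test_empty_contour_list_rejected(self):
        ss = StructureSet({"PTV": []})
        with pytest.raises(ValueError):
            rasterize_structure(ss, "PTV", grid(np.zeros((2, 4, 4))))

    def test_agrees_with_point_in_polygon_oracle(self, rng):
        ct = grid(np.zeros((1, 14, 14)))
        for _ in range(20):
            n_vert = rng.integers(3, 13)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
            r = rng.uniform(2.0, 6.0)
            cx, cy = rng.uniform(5, 9, 2)
            poly = np.stack([cx + r * np.cos(angles), cy + r * np.sin(angles)], axis=1)
            snapped = np.rint(poly)
            ss = StructureSet({"PTV": [(0.0, poly)]})
            mask = rasterize_structure(ss, "PTV", ct).values[0]
            for row in range(14):
                for col in range(14):
                    assert mask[row, col] == _ray_cast_inside(snapped, col, row), (
                        f"voxel ({row},{col}) disagrees with oracle")


class TestParotidCenter:
    def ct(self):
        return grid(np.zeros((60, 4, 4)))

    def entries(self, z_list):
        poly = np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float)
        return [(float(z), poly) for z in z_list]

    def test_symmetric_span_midpoint(self):
        ss = StructureSet({"Parotid_L": self.entries(range(30, 51)),
                           "Parotid_R": self.entries(range(30, 51))})
        assert parotid_axial_center(ss, self.ct()) == 40

    def test_union_of_asymmetric_spans(self):
        ss = StructureSet({"Parotid_L": self.entries(range(30, 41)),
                           "Parotid_R": self.entries(range(34, 51))})
        assert parotid_axial_center(ss, self.ct()) == 40

    def test_single_slice(self):
        ss = StructureSet({"Parotid_L": self.entries([17]),
                           "Parotid_R": self.entries([17])})
        assert parotid_axial_center(ss, self.ct()) == 17

    def test_missing_parotid_error(self):
        ss = StructureSet({"Parotid_L": self.entries([5])})
        with pytest.raises(ValueError):
            parotid_axial_center(ss, self.ct())


class TestCrop:
    def test_identity_when_window_matches(self, rng):
        x = rng.random((8, 10, 12, 3))
        out = crop_volume(x, center_axial=4, window=(8, 10, 12))
        assert np.array_equal(out, x)

    def test_edge_center_zero_pads(self, rng):
        x = rng.random((8, 6, 6, 3)) + 0.5
        out = crop_volume(x, center_axial=0, window=(8, 6, 6))
        assert np.all(out[:4] == 0)          # window extends below the source
        assert np.all(out[4:] > 0)           # source slices land in the top half

    def test_overlap_voxel_count(self):
        x = np.ones((6, 6, 6, 1))
        out = crop_volume(x, center_axial=3, window=(10, 10, 10))
        assert out.sum() == 6 * 6 * 6


class TestNormalize:
    @pytest.mark.parametrize("hu,expected", [(250.0, 1.0), (50.0, 0.5),
                                             (-1000.0, 0.0), (-150.0, 0.0)])
    def test_hu_window(self, hu, expected):
        out = hu_window_normalize(grid(np.full((1, 1, 1), hu)))
        assert out.values[0, 0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("gy,expected", [(70.0, 1.0), (0.0, 0.0), (35.0, 0.5)])
    def test_dose_scaling(self, gy, expected):
        out = dose_normalize(grid(np.full((1, 1, 1), gy)))
        assert out.values[0, 0, 0] == pytest.approx(expected)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_normalize(grid(np.full((1, 1, 1), -1.0)))


class TestMirrorAndAssemble:
    def vol(self, rng):
        return MultiChannelVolume(rng.random((4, 5, 6, 3)).astype(np.float32),
                                  (1, 1, 1), "p1")

    def test_mirror_is_involution(self, rng):
        v = self.vol(rng)
        twice = sagittal_mirror(sagittal_mirror(v, "left"), "left")
        assert np.array_equal(twice.values, v.values)
        assert not twice.mirrored

    def test_centroid_flips(self, rng):
        v = self.vol(rng)
        mask = np.zeros((4, 5, 6, 3), dtype=np.float32)
        mask[2, 2, 1, 2] = 1.0
        v = MultiChannelVolume(mask, (1, 1, 1), "p")
        m = sagittal_mirror(v, "left")
        assert m.values[2, 2, 6 - 1 - 1, 2] == 1.0

    def test_right_side_untouched(self, rng):
        v = self.vol(rng)
        out = sagittal_mirror(v, "right")
        assert out is v

    def test_channel_order(self, rng):
        ct = grid(rng.random((3, 4, 5)))
        dose = grid(rng.random((3, 4, 5)))
        mask = grid((rng.random((3, 4, 5)) > 0.5).astype(float))
        out = assemble_channels(ct, dose, mask)
        assert np.array_equal(out[..., 2], mask.values)
        assert np.array_equal(out[..., 0], ct.values)

    def test_shape_mismatch_error(self, rng):
        with pytest.raises(ValueError, match="shape"):
            assemble_channels(grid(np.zeros((3, 4, 5))), grid(np.zeros((3, 4, 5))),
                              grid(np.zeros((3, 4, 4))))
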