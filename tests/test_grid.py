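"""Grid-to-model-frame mapping, whole-grid dose cubes and voxel masks."""

import numpy as np
import pytest

import peridose as pdx
from peridose.exceptions import ConfigurationError, InvalidInputError
from peridose.grid import interpolate_at_point, voxel_coords_in_model_frame


def small_grid(n=5, spacing=1.0, origin=None):
    if origin is None:
        origin = -(n - 1) / 2 * spacing
    return pdx.DoseGrid(
        np.zeros((n, n, n)), spacing=(spacing,) * 3, origin=(origin,) * 3
    )


class TestFrameMapping:
    def test_isocenter_voxel_maps_to_origin(self):
        grid = small_grid(5)
        frame = pdx.IsocenterFrame(isocenter=(0.0, 0.0, 0.0))
        x, y, z = voxel_coords_in_model_frame(grid, frame)
        assert x[2, 2, 2] == y[2, 2, 2] == z[2, 2, 2] == 0.0

    def test_identity_map_gives_index_offsets(self):
        grid = pdx.DoseGrid(np.zeros((3, 3, 3)), spacing=(1, 1, 1), origin=(0, 0, 0))
        frame = pdx.IsocenterFrame(isocenter=(0.0, 0.0, 0.0))
        x, y, z = voxel_coords_in_model_frame(grid, frame)
        i, j, k = np.indices((3, 3, 3))
        assert np.array_equal(x, i) and np.array_equal(y, j) and np.array_equal(z, k)

    def test_z_flip_preserves_abs_z(self):
        grid = small_grid(5)
        plus = pdx.IsocenterFrame(axis_map=(1, 2, 3))
        minus = pdx.IsocenterFrame(axis_map=(1, 2, -3))
        _, _, z1 = voxel_coords_in_model_frame(grid, plus)
        _, _, z2 = voxel_coords_in_model_frame(grid, minus)
        assert np.array_equal(np.abs(z1), np.abs(z2))

    def test_invalid_axis_map_rejected(self):
        with pytest.raises(ConfigurationError):
            pdx.IsocenterFrame(axis_map=(1, 1, 3))


class TestComputeCube:
    def test_matches_point_evaluation_voxel_by_voxel(self):
        grid = pdx.DoseGrid(
            np.zeros((7, 6, 8)), spacing=(3, 4, 5), origin=(-9, -10, -17.5)
        )
        frame = pdx.IsocenterFrame(isocenter=(0.5, -1.0, 0.25), axis_map=(2, -1, 3))
        cube = pdx.compute_ppd_cube(grid, frame)
        x, y, z = voxel_coords_in_model_frame(grid, frame)
        rng = np.random.default_rng(3)
        for _ in range(40):
            i, j, k = (rng.integers(0, d) for d in grid.dims)
            if not cube.valid[i, j, k]:
                continue
            assert cube.values[i, j, k] == pytest.approx(
                pdx.ppd_at_point(x[i, j, k], y[i, j, k], z[i, j, k]), rel=1e-12
            )

    def test_leakage_plateau_cube(self):
        grid = pdx.DoseGrid(
            np.zeros((3, 3, 3)), spacing=(5, 5, 5), origin=(60, 60, 60)
        )
        cube = pdx.compute_ppd_cube(grid, pdx.IsocenterFrame())
        assert np.all(cube.values == pdx.TreatmentParameters().L_u)

    def test_corner_voxels_match_hand_evaluation(self):
        grid = pdx.DoseGrid(np.zeros((3, 3, 3)), spacing=(10, 10, 10), origin=(-10,) * 3)
        cube = pdx.compute_ppd_cube(grid, pdx.IsocenterFrame())
        r = np.sqrt(300.0)
        expected = (37.890 - 0.679 * 10) * np.exp(-0.007 * r) / 300.0
        assert cube.values[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert cube.values[2, 2, 2] == pytest.approx(expected, rel=1e-12)

    def test_full_exclusion_mask_gives_all_sentinel(self):
        grid = small_grid(3, spacing=10.0)
        cube = pdx.compute_ppd_cube(
            grid, pdx.IsocenterFrame(), exclusion_mask=np.ones((3, 3, 3), bool)
        )
        assert np.all(np.isnan(cube.values))
        assert not cube.valid.any()

    def test_isocenter_voxel_is_sentinel_not_huge(self):
        grid = small_grid(5, spacing=2.0)
        cube = pdx.compute_ppd_cube(grid, pdx.IsocenterFrame())
        assert np.isnan(cube.values[2, 2, 2])
        assert not cube.valid[2, 2, 2]

    def test_invariant_under_transverse_axis_relabelling(self):
        """Swapping which grid axis is AP vs LR cannot change the dose."""
        grid = pdx.DoseGrid(
            np.zeros((5, 5, 5)), spacing=(2, 2, 2), origin=(-4, -4, 26)
        )
        a = pdx.compute_ppd_cube(grid, pdx.IsocenterFrame(axis_map=(1, 2, 3)))
        b = pdx.compute_ppd_cube(grid, pdx.IsocenterFrame(axis_map=(-2, 1, 3)))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)


class TestInFieldMask:
    def test_threshold_relative_to_isocenter_dose(self):
        values = np.zeros((5, 5, 5))
        values[2, 2, 2] = 100.0
        values[0, 0, 0] = 5.0
        values[4, 4, 4] = 4.999
        grid = small_grid(5)
        grid = grid.like(values)
        mask = pdx.in_field_mask(grid, pdx.IsocenterFrame(), fraction=0.05)
        assert mask[2, 2, 2] and mask[0, 0, 0] and not mask[4, 4, 4]

    def test_uniform_cube_entirely_in_field(self):
        grid = small_grid(4).like(np.full((4, 4, 4), 7.0))
        frame = pdx.IsocenterFrame(isocenter=(0.2, -0.1, 0.3))
        assert pdx.in_field_mask(grid, frame).all()

    def test_spherical_decay_mask_radius_matches_analytic_crossing(self):
        # dose = exp(-r^2 / (2 sigma^2)): the 5% crossing is at
        # r = sigma * sqrt(2 ln 20)
        n, sp, sigma = 41, 0.5, 3.0
        grid = small_grid(n, spacing=sp)
        x, y, z = voxel_coords_in_model_frame(grid, pdx.IsocenterFrame())
        r = np.sqrt(x * x + y * y + z * z)
        grid = grid.like(np.exp(-(r**2) / (2 * sigma**2)))
        mask = pdx.in_field_mask(grid, pdx.IsocenterFrame(), fraction=0.05)
        r_cross = sigma * np.sqrt(2 * np.log(20.0))
        assert np.all(mask[r <= r_cross - sp])
        assert not mask[r > r_cross + sp].any()

    def test_monotone_in_fraction(self):
        rng = np.random.default_rng(5)
        grid = small_grid(9).like(rng.random((9, 9, 9)) + 0.1)
        frame = pdx.IsocenterFrame()
        loose = pdx.in_field_mask(grid, frame, fraction=0.05)
        tight = pdx.in_field_mask(grid, frame, fraction=0.50)
        assert np.all(loose[tight])  # tight mask is a subset

    def test_zero_isocenter_dose_rejected(self):
        grid = small_grid(5)
        with pytest.raises(InvalidInputError):
            pdx.in_field_mask(grid, pdx.IsocenterFrame())

    def test_trilinear_interpolation_at_off_center_isocenter(self):
        grid = pdx.DoseGrid(np.zeros((2, 1, 1)), spacing=(1, 1, 1), origin=(0, 0, 0))
        grid = grid.like(np.array([[[1.0]], [[3.0]]]))
        assert interpolate_at_point(grid, (0.5, 0, 0)) == pytest.approx(2.0)


class TestBodyInteriorMask:
    def brute_force_erosion(self, mask):
        out = np.zeros_like(mask)
        n = mask.shape
        for i in range(n[0]):
            for j in range(n[1]):
                for k in range(n[2]):
                    if not mask[i, j, k]:
                        continue
                    keep = True
                    for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                        ii, jj, kk = i + di, j + dj, k + dk
                        if not (0 <= ii < n[0] and 0 <= jj < n[1] and 0 <= kk < n[2]):
                            keep = False
                            break
                        if not mask[ii, jj, kk]:
                            keep = False
                            break
                    out[i, j, k] = keep
        return out

    def test_3x3x3_block_keeps_only_center(self):
        mask = np.ones((3, 3, 3), bool)
        eroded = pdx.body_interior_mask(mask)
        assert eroded.sum() == 1 and eroded[1, 1, 1]

    def test_5x5x5_block_keeps_inner_3x3x3(self):
        mask = np.ones((5, 5, 5), bool)
        eroded = pdx.body_interior_mask(mask)
        expected = np.zeros((5, 5, 5), bool)
        expected[1:4, 1:4, 1:4] = True
        assert np.array_equal(eroded, expected)

    def test_empty_mask_stays_empty(self):
        assert not pdx.body_interior_mask(np.zeros((4, 4, 4), bool)).any()

    def test_matches_brute_force_on_random_mask(self):
        rng = np.random.default_rng(17)
        mask = rng.random((7, 7, 7)) > 0.35
        assert np.array_equal(
            pdx.body_interior_mask(mask), self.brute_force_erosion(mask)
        )
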