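"""Coefficient fitting, voxel selection and agreement statistics."""

import numpy as np
import pytest

import peridose as pdx
from peridose.calibration import DEFAULT_START
from peridose.exceptions import FitInfeasibleError, InvalidInputError
from peridose.grid import voxel_coords_in_model_frame

TRUE = pdx.ModelCoefficients()  # A1=37.890, A2=0.679, A3=0.007


class TestCalibrationMask:
    def test_composition_on_synthetic_phantom(self, phantom_spec, phantom):
        body, _, _ = phantom
        ref = pdx.generate_reference_dose(phantom_spec, noise_cv=0.0)
        mask = pdx.calibration_mask(ref, phantom_spec.frame, body)
        x, y, z = voxel_coords_in_model_frame(ref, phantom_spec.frame)
        r = np.sqrt(x * x + y * y + z * z)
        # in-field blob voxels excluded
        infield = pdx.in_field_mask(ref, phantom_spec.frame, 0.05)
        assert not (mask & infield).any()
        # the surface shell is excluded
        assert not (mask & ~pdx.body_interior_mask(body)).any()
        # radial band respected
        assert r[mask].max() <= 40.0 and r[mask].min() >= 1.0
        assert mask.sum() > 100

    def test_r_beyond_cutoff_excluded(self):
        # a grid reaching past 40 cm: no masked voxel beyond the cutoff
        grid = pdx.DoseGrid(np.zeros((45, 3, 3)), spacing=(2, 2, 2), origin=(-10, -2, -2))
        vals = np.full(grid.dims, 0.01)
        vals[5, 1, 1] = 10.0  # in-field spike at the isocenter
        ref = grid.like(vals)
        frame = pdx.IsocenterFrame()
        mask = pdx.calibration_mask(ref, frame, np.ones(grid.dims, bool))
        x, y, z = voxel_coords_in_model_frame(ref, frame)
        r = np.sqrt(x * x + y * y + z * z)
        assert (r[mask] <= 40.0).all()
        assert (r > 40).any()  # the fixture does reach beyond the cutoff

    def test_empty_mask_raises(self):
        grid = pdx.DoseGrid(np.ones((3, 3, 3)), spacing=(1, 1, 1), origin=(-1, -1, -1))
        with pytest.raises(FitInfeasibleError):
            pdx.calibration_mask(grid, pdx.IsocenterFrame(), np.zeros((3, 3, 3), bool))


class TestFitCoefficients:
    def test_noiseless_recovery_to_0p1_percent(self, noiseless_fit):
        fit = noiseless_fit
        assert fit.converged
        assert fit.coefficients.A1 == pytest.approx(TRUE.A1, rel=1e-3)
        assert fit.coefficients.A2 == pytest.approx(TRUE.A2, rel=1e-3)
        assert fit.coefficients.A3 == pytest.approx(TRUE.A3, rel=1e-3)

    def test_noisy_recovery_within_published_uncertainties(
        self, recovery_grid, noiseless_reference
    ):
        grid, frame, mask = recovery_grid
        rng = np.random.default_rng(123)
        noisy = noiseless_reference.like(
            noiseless_reference.values
            * (1.0 + 0.05 * rng.standard_normal(noiseless_reference.values.shape))
        )
        fit = pdx.fit_coefficients(noisy, mask, frame=frame)
        assert abs(fit.coefficients.A1 - TRUE.A1) < 1.415
        assert abs(fit.coefficients.A2 - TRUE.A2) < 0.074
        assert abs(fit.coefficients.A3 - TRUE.A3) < 0.004

    @pytest.mark.parametrize("factor", [0.5, 0.8, 1.5])
    def test_recovery_from_perturbed_starts(
        self, recovery_grid, noiseless_reference, factor
    ):
        grid, frame, mask = recovery_grid
        start = TRUE.as_array() * factor
        fit = pdx.fit_coefficients(noiseless_reference, mask, frame=frame, start=start)
        np.testing.assert_allclose(fit.coefficients.as_array(), TRUE.as_array(), rtol=1e-3)

    def test_deterministic_for_fixed_start(self, recovery_grid, noiseless_reference):
        grid, frame, mask = recovery_grid
        f1 = pdx.fit_coefficients(noiseless_reference, mask, frame=frame)
        f2 = pdx.fit_coefficients(noiseless_reference, mask, frame=frame)
        assert np.array_equal(f1.coefficients.as_array(), f2.coefficients.as_array())
        assert f1.start == DEFAULT_START

    def test_empty_mask_raises(self, noiseless_reference):
        with pytest.raises(FitInfeasibleError):
            pdx.fit_coefficients(
                noiseless_reference, np.zeros(noiseless_reference.dims, bool)
            )

    def test_non_positive_reference_rejected(self, recovery_grid, noiseless_reference):
        grid, frame, mask = recovery_grid
        bad = noiseless_reference.like(np.zeros(noiseless_reference.dims))
        with pytest.raises(InvalidInputError):
            pdx.fit_coefficients(bad, mask, frame=frame)

    def test_absolute_loss_also_recovers_noiseless(
        self, recovery_grid, noiseless_reference
    ):
        grid, frame, mask = recovery_grid
        fit = pdx.fit_coefficients(
            noiseless_reference, mask, frame=frame, loss="absolute"
        )
        np.testing.assert_allclose(
            fit.coefficients.as_array(), TRUE.as_array(), rtol=1e-2
        )


class TestAgreementStats:
    def make(self, values):
        return pdx.DoseGrid(values, spacing=(1, 1, 1), origin=(0, 0, 0))

    def test_identical_cubes_give_zeros(self):
        a = self.make(np.random.default_rng(0).random((3, 3, 3)) + 0.5)
        stats = pdx.agreement_stats(a, a, np.ones(a.dims, bool))
        assert stats.p95_abs_pct_diff == 0.0
        assert stats.mean_abs_pct_diff == 0.0
        assert stats.max_abs_diff == 0.0

    def test_ten_percent_scaling(self):
        ref = self.make(np.random.default_rng(1).random((4, 4, 4)) + 0.5)
        model = self.make(np.asarray(ref.values) * 1.1)
        stats = pdx.agreement_stats(model, ref, np.ones(ref.dims, bool))
        assert stats.p95_abs_pct_diff == pytest.approx(10.0)
        assert stats.mean_abs_pct_diff == pytest.approx(10.0)
        assert stats.max_abs_diff == pytest.approx(0.1 * np.max(ref.values))

    def test_matches_brute_force_on_twenty_voxels(self):
        rng = np.random.default_rng(7)
        ref_vals = rng.random(20) + 0.2
        model_vals = ref_vals * (1 + 0.3 * rng.standard_normal(20))
        ref = self.make(ref_vals.reshape(20, 1, 1))
        model = self.make(model_vals.reshape(20, 1, 1))
        stats = pdx.agreement_stats(model, ref, np.ones((20, 1, 1), bool))
        # brute-force recomputation with plain python
        pct = sorted(
            abs(m - r) / r * 100.0 for m, r in zip(model_vals, ref_vals)
        )
        mean = sum(pct) / len(pct)
        mx = max(abs(m - r) for m, r in zip(model_vals, ref_vals))
        assert stats.mean_abs_pct_diff == pytest.approx(mean, rel=1e-12)
        assert stats.max_abs_diff == pytest.approx(mx, rel=1e-12)
        assert stats.p95_abs_pct_diff == pytest.approx(
            float(np.percentile(pct, 95)), rel=1e-12
        )

    def test_scale_invariance_under_common_rescaling(self):
        rng = np.random.default_rng(9)
        ref = self.make(rng.random((4, 4, 4)) + 0.5)
        model = self.make(np.asarray(ref.values) * (1 + 0.1 * rng.standard_normal((4, 4, 4))))
        mask = np.ones(ref.dims, bool)
        s1 = pdx.agreement_stats(model, ref, mask)
        s2 = pdx.agreement_stats(
            self.make(np.asarray(model.values) * 55.0),
            self.make(np.asarray(ref.values) * 55.0),
            mask,
        )
        assert s1.mean_abs_pct_diff == pytest.approx(s2.mean_abs_pct_diff)
        assert s1.p95_abs_pct_diff == pytest.approx(s2.p95_abs_pct_diff)

    def test_zero_reference_rejected(self):
        ref = self.make(np.zeros((2, 2, 2)))
        model = self.make(np.ones((2, 2, 2)))
        with pytest.raises(InvalidInputError):
            pdx.agreement_stats(model, ref, np.ones((2, 2, 2), bool))


class TestComparePointDoses:
    def test_prostate_style_pair_difference(self):
        # the worst point of a prostate validation: 31.4 predicted vs 47.2
        # measured (mGy/Gy) differ by 15.8 mGy/Gy
        stats = pdx.compare_point_doses(
            [((10, 0, 20), 31.4)], [((10, 0, 20), 47.2)]
        )
        assert stats.max_abs_diff == pytest.approx(15.8, abs=1e-9)

    def test_lung_style_pair_difference(self):
        # 14.1 predicted vs 49.0 simulated (mGy/Gy): 34.9 mGy/Gy apart
        stats = pdx.compare_point_doses(
            [((0, 0, -35), 14.1)], [((0, 0, -35), 49.0)]
        )
        assert stats.max_abs_diff == pytest.approx(34.9, abs=1e-9)

    def test_identical_lists_give_zeros(self):
        pts = [((1.0, 2.0, 3.0), 5.0), ((4.0, 5.0, 6.0), 7.0)]
        stats = pdx.compare_point_doses(pts, pts)
        assert stats.mean_abs_pct_diff == 0.0
        assert stats.max_abs_diff == 0.0
        assert len(stats.per_point) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            pdx.compare_point_doses([((0, 0, 10), 1.0)], [])

    def test_point_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            pdx.compare_point_doses(
                [((0, 0, 10), 1.0)], [((0, 0, 11), 1.0)]
            )
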