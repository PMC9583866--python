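"""Model/Results interface for calibrating and applying the peripheral dose model.

:class:`PeripheralDoseModel` wraps a reference 3D dose distribution (plus
body mask and isocenter frame) and owns the calibration problem; ``fit()``
returns a :class:`PeripheralDoseResults` carrying the fitted coefficients,
approximate standard errors, the agreement diagnostics against the
reference, and a ``summary()`` table.  Prediction (point doses, whole-grid
dose cubes, organ DVHs) and plotting hang off the results object.

    >>> model = PeripheralDoseModel(reference, frame, body_mask=body)
    >>> res = model.fit()
    >>> print(res.summary())
    >>> cube = res.predict_cube(reference, frame)
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

from .calibration import (
    AgreementStats,
    DEFAULT_START,
    FitResult,
    agreement_stats,
    calibration_mask,
    fit_coefficients,
)
from .core import (
    ModelCoefficients,
    ReferenceConstants,
    TreatmentParameters,
    ppd_at_point,
    ppd_at_points,
)
from .dvh import DVHCurve, OrganMask, cumulative_dvh
from .exceptions import InvalidInputError
from .grid import DoseGrid, IsocenterFrame, compute_ppd_cube, voxel_coords_in_model_frame

__all__ = ["PeripheralDoseModel", "PeripheralDoseResults"]


class PeripheralDoseModel:
    """Out-of-field photon dose model bound to a reference dose distribution.

    Parameters
    ----------
    reference : DoseGrid
        Reference 3D dose distribution in mGy/MU (e.g. a Monte Carlo cube of
        the reference plan).
    frame : IsocenterFrame
        Isocenter position and anatomical axis mapping for the grid.
    body_mask : ndarray of bool, optional
        Body voxels; defaults to the whole grid.  The fit uses the eroded
        interior (surface shell excluded).
    tps_dose : DoseGrid, optional
        In-field dose distribution used to build the 5 % isodose exclusion;
        defaults to the reference cube itself.
    params, ref_constants
        Treatment parameters (the calibration plan has epsilon = F = 1 and
        L_u = L_r by construction) and reference constants.
    mask : ndarray of bool, optional
        Explicit calibration mask; when given it replaces the standard
        construction (body interior ∧ outside the in-field isodose ∧ radial
        band).  Useful when the reference has no in-field region at all.
    """

    def __init__(
        self,
        reference: DoseGrid,
        frame: IsocenterFrame = IsocenterFrame(),
        body_mask: Optional[np.ndarray] = None,
        tps_dose: Optional[DoseGrid] = None,
        params: TreatmentParameters = TreatmentParameters(),
        ref_constants: ReferenceConstants = ReferenceConstants(),
        mask: Optional[np.ndarray] = None,
    ) -> None:
        self.reference = reference
        self.frame = frame
        self.params = params
        self.ref_constants = ref_constants
        if body_mask is None:
            # pad-free full-grid body: erosion still strips the outer shell
            body_mask = np.ones(reference.dims, dtype=bool)
        self.body_mask = np.asarray(body_mask, bool)
        self.tps_dose = tps_dose
        if mask is not None:
            self.mask = np.asarray(mask, bool)
            if self.mask.shape != reference.dims or not self.mask.any():
                raise InvalidInputError("explicit mask must match the grid and be non-empty")
        else:
            self.mask = calibration_mask(
                reference, frame, self.body_mask, ref_constants, tps_dose
            )

    @classmethod
    def from_3ddose(cls, path, frame: IsocenterFrame = IsocenterFrame(), **kwargs):
        """Build the model from a DOSXYZnrc ``.3ddose`` reference cube."""
        from .io import read_3ddose

        return cls(read_3ddose(path), frame, **kwargs)

    def fit(
        self,
        start: Sequence[float] = DEFAULT_START,
        loss: str = "relative",
        **options,
    ) -> "PeripheralDoseResults":
        """Fit A1, A2, A3 by Nelder–Mead and return a results object."""
        fit = fit_coefficients(
            self.reference,
            self.mask,
            frame=self.frame,
            params=self.params,
            ref_constants=self.ref_constants,
            start=start,
            loss=loss,
            **options,
        )
        return PeripheralDoseResults(self, fit)


class PeripheralDoseResults:
    """Fitted peripheral dose model: estimates, uncertainties, predictions."""

    def __init__(self, model: PeripheralDoseModel, fit: FitResult) -> None:
        self.model = model
        self.fit_result = fit
        self.coefficients: ModelCoefficients = fit.coefficients
        self.bse = fit.bse
        self.converged = fit.converged
        self.objective_value = fit.objective_value
        self.n_voxels = fit.n_voxels

    @property
    def params(self) -> np.ndarray:
        """Fitted coefficient vector (A1, A2, A3)."""
        return self.coefficients.as_array()

    # ------------------------------------------------------------------
    # prediction
    # ------------------------------------------------------------------

    def predict(
        self,
        points: np.ndarray,
        treatment: Optional[TreatmentParameters] = None,
    ) -> np.ndarray:
        """Peripheral dose per MU (mGy/MU) at (n, 3) isocenter-frame points."""
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.shape[1] != 3:
            raise InvalidInputError("points must have shape (n, 3)")
        treatment = treatment or self.model.params
        return np.asarray(
            ppd_at_points(
                pts[:, 0], pts[:, 1], pts[:, 2],
                treatment, self.model.ref_constants, self.coefficients,
            )
        )

    def predict_cube(
        self,
        grid: Optional[DoseGrid] = None,
        frame: Optional[IsocenterFrame] = None,
        treatment: Optional[TreatmentParameters] = None,
        exclusion_mask: Optional[np.ndarray] = None,
    ) -> DoseGrid:
        """Whole-grid dose cube (mGy/MU) using the fitted coefficients."""
        grid = grid if grid is not None else self.model.reference
        frame = frame if frame is not None else self.model.frame
        return compute_ppd_cube(
            grid,
            frame,
            treatment or self.model.params,
            self.model.ref_constants,
            self.coefficients,
            exclusion_mask=exclusion_mask,
        )

    def dvh(
        self,
        organ: OrganMask,
        cube: Optional[DoseGrid] = None,
        bin_width: float = 0.1,
    ) -> DVHCurve:
        """Cumulative DVH of an organ on a (default: freshly predicted) cube."""
        if cube is None:
            cube = self.predict_cube()
        return cumulative_dvh(cube, organ, bin_width=bin_width)

    # ------------------------------------------------------------------
    # diagnostics
    # ------------------------------------------------------------------

    def agreement(self) -> AgreementStats:
        """Model-vs-reference agreement statistics on the calibration mask."""
        cube = self.predict_cube()
        return agreement_stats(cube, self.model.reference, self.model.mask)

    def summary(self) -> str:
        """A plain-text summary table of the fit."""
        names = ["A1 (mGy cm2/MU)", "A2 (mGy cm/MU)", "A3 (1/cm)"]
        stats = self.agreement()
        lines = [
            "Peripheral photon dose model — calibration fit",
            "=" * 58,
            f"{'n voxels':<28}{self.n_voxels:>12}",
            f"{'objective (sum sq. resid)':<28}{self.objective_value:>12.6g}",
            f"{'converged':<28}{str(self.converged):>12}",
            f"{'iterations':<28}{self.fit_result.n_iterations:>12}",
            "-" * 58,
            f"{'coefficient':<20}{'estimate':>14}{'approx. s.e.':>16}",
        ]
        for i, name in enumerate(names):
            se = f"{self.bse[i]:.4g}" if self.bse is not None else "n/a"
            lines.append(f"{name:<20}{self.params[i]:>14.6g}{se:>16}")
        lines += [
            "-" * 58,
            "agreement vs reference on the calibration region:",
            f"{'  mean |diff| (%)':<28}{stats.mean_abs_pct_diff:>12.3g}",
            f"{'  95th pct |diff| (%)':<28}{stats.p95_abs_pct_diff:>12.3g}",
            f"{'  max |diff| (mGy/MU)':<28}{stats.max_abs_diff:>12.3g}",
            "=" * 58,
        ]
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # plotting
    # ------------------------------------------------------------------

    def plot_falloff(self, axis: str = "z", rmax: float = 45.0, ax=None):
        """Dose per isocenter Gy vs distance along one anatomical axis."""
        import matplotlib.pyplot as plt

        from .core import normalize_to_isocenter_dose

        if ax is None:
            _, ax = plt.subplots()
        idx = {"x": 0, "y": 1, "z": 2}[axis]
        r = np.linspace(1.5, rmax, 200)
        pts = np.zeros((r.size, 3))
        pts[:, idx] = r
        per_mu = self.predict(pts)
        t = self.model.params
        ax.semilogy(
            r, normalize_to_isocenter_dose(per_mu, t.total_MU, t.prescription)
        )
        ax.set_xlabel(f"distance from isocenter along {axis} (cm)")
        ax.set_ylabel("peripheral dose (mGy) per isocenter dose (Gy)")
        return ax
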