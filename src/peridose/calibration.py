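"""Calibration of the three model coefficients against a reference dose cube.

The coefficients A1 (scatter amplitude), A2 (craniocaudal gradient) and A3
(effective attenuation) are fitted to a reference 3D dose distribution —
typically a Monte Carlo cube of the reference plan, with the correction
factors frozen at epsilon = F = 1 and L_u = L_r — by a derivative-free
Nelder–Mead simplex search.

The default objective is the sum of squared *relative* residuals
``((model - ref) / ref)^2``: peripheral dose spans about two orders of
magnitude over the fitted region, and an absolute least-squares loss would
be dominated by the near-field voxels.  Absolute squared error and inverse-
variance weighting by the reference's relative-error array are available as
options.

Fitted voxels are restricted to the body interior (one-voxel surface shell
eroded away), outside the in-field isodose region, and within the radial
band where the scatter branch applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .core import (
    ModelCoefficients,
    ReferenceConstants,
    TreatmentParameters,
    R_MIN_CM,
    ppd_at_points,
)
from .exceptions import FitInfeasibleError, InvalidInputError
from .grid import (
    DoseGrid,
    IsocenterFrame,
    body_interior_mask,
    in_field_mask,
    voxel_coords_in_model_frame,
)

__all__ = [
    "FitResult",
    "AgreementStats",
    "calibration_mask",
    "fit_coefficients",
    "agreement_stats",
    "compare_point_doses",
    "DEFAULT_START",
]

#: Default simplex starting point (A1, A2, A3); deliberately far from the
#: calibrated values so recovery tests are non-trivial.
DEFAULT_START = (20.0, 0.3, 0.02)


@dataclass
class FitResult:
    """Outcome of a coefficient fit."""

    coefficients: ModelCoefficients
    objective_value: float
    n_voxels: int
    converged: bool
    start: Tuple[float, float, float]
    n_iterations: int = 0
    message: str = ""
    bse: Optional[np.ndarray] = None  # approximate standard errors (A1, A2, A3)

    def __post_init__(self) -> None:
        if self.converged and self.n_voxels <= 0:
            raise InvalidInputError("a converged fit must have used > 0 voxels")
        if self.objective_value < 0:
            raise InvalidInputError("objective_value must be >= 0")


@dataclass
class AgreementStats:
    """Model-vs-reference agreement statistics.

    ``p95_abs_pct_diff`` and ``mean_abs_pct_diff`` are statistics of the
    per-point absolute percentage difference relative to the reference;
    ``max_abs_diff`` is the largest absolute difference in dose units.
    """

    p95_abs_pct_diff: float
    mean_abs_pct_diff: float
    max_abs_diff: float
    n_points: int
    per_point: Optional[pd.DataFrame] = None


def calibration_mask(
    reference: DoseGrid,
    frame: IsocenterFrame,
    body_mask: np.ndarray,
    ref_constants: ReferenceConstants = ReferenceConstants(),
    tps_dose: Optional[DoseGrid] = None,
) -> np.ndarray:
    """Voxel mask selecting the calibration region.

    Keeps voxels that are (a) strictly inside the body (surface shell
    eroded), (b) outside the in-field isodose region of ``tps_dose`` (the
    reference cube itself when no separate TPS dose is given), and (c) in
    the radial band ``R_MIN_CM <= r <= r_cut`` where the scatter branch of
    the model applies.
    """
    body_mask = np.asarray(body_mask, bool)
    if body_mask.shape != reference.dims:
        raise InvalidInputError("body_mask dims must match the reference grid")
    if tps_dose is None:
        tps_dose = reference
    x, y, z = voxel_coords_in_model_frame(reference, frame)
    r = np.sqrt(x * x + y * y + z * z)
    mask = (
        body_interior_mask(body_mask)
        & ~in_field_mask(tps_dose, frame, ref_constants.isodose_exclusion)
        & (r <= ref_constants.r_cut)
        & (r >= R_MIN_CM)
    )
    if not mask.any():
        raise FitInfeasibleError(
            "calibration mask is empty: no voxel is simultaneously inside the "
            "body interior, outside the in-field region and within the radial band"
        )
    return mask


def _objective_factory(
    data: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    params: TreatmentParameters,
    ref: ReferenceConstants,
    loss: str,
    weights: Optional[np.ndarray],
):
    absz = np.abs(z)
    r = np.sqrt(x * x + y * y + z * z)
    r2 = r * r
    eps_F = (params.E_U / ref.E_R) * (params.F_U / ref.F_R)
    dL = params.L_u - ref.L_r

    def model(theta: np.ndarray) -> np.ndarray:
        a1, a2, a3 = theta
        return np.maximum(eps_F * (a1 - a2 * absz) * np.exp(-a3 * r) / r2 + dL, 0.0)

    if loss == "relative":
        def residuals(theta):
            return (model(theta) - data) / data
    elif loss == "absolute":
        def residuals(theta):
            return model(theta) - data
    else:
        raise InvalidInputError(f"unknown loss {loss!r}; use 'relative' or 'absolute'")

    def objective(theta: np.ndarray) -> float:
        res = residuals(theta)
        if weights is not None:
            res = res * np.sqrt(weights)
        val = float(np.dot(res, res))
        return val if np.isfinite(val) else np.inf

    return model, residuals, objective


def fit_coefficients(
    reference: DoseGrid,
    mask: np.ndarray,
    frame: IsocenterFrame = IsocenterFrame(),
    params: TreatmentParameters = TreatmentParameters(),
    ref_constants: ReferenceConstants = ReferenceConstants(),
    start: Sequence[float] = DEFAULT_START,
    loss: str = "relative",
    weight_by_rel_error: bool = False,
    xatol: float = 1e-8,
    fatol: float = 1e-8,
    maxiter: int = 5000,
) -> FitResult:
    """Fit A1, A2, A3 to the masked voxels of a reference dose cube (mGy/MU).

    Deterministic for fixed ``start`` and options (Nelder–Mead simplex).
    Non-convergence within ``maxiter`` returns a result flagged
    ``converged=False`` with the best coefficients found.

    ``weight_by_rel_error=True`` weights the squared residuals by the inverse
    variance implied by the reference's per-voxel relative error (off by
    default).
    """
    mask = np.asarray(mask, bool)
    if mask.shape != reference.dims:
        raise InvalidInputError("mask dims must match the reference grid")
    if not mask.any():
        raise FitInfeasibleError("cannot fit on an empty voxel mask")
    data = np.asarray(reference.values, float)[mask]
    if np.any(~np.isfinite(data)) or np.any(data <= 0):
        raise InvalidInputError(
            "reference dose must be finite and > 0 on every masked voxel"
        )
    x, y, z = voxel_coords_in_model_frame(reference, frame)
    x, y, z = x[mask], y[mask], z[mask]

    weights = None
    if weight_by_rel_error:
        if reference.rel_error is None:
            raise InvalidInputError("weight_by_rel_error requires a rel_error array")
        sigma = reference.rel_error[mask]
        if np.any(sigma <= 0):
            raise InvalidInputError("rel_error must be > 0 on the mask for weighting")
        weights = 1.0 / sigma**2

    _, residuals, objective = _objective_factory(
        data, x, y, z, params, ref_constants, loss, weights
    )

    res = optimize.minimize(
        objective,
        np.asarray(start, float),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "maxfev": 4 * maxiter},
    )
    coeffs = ModelCoefficients(*[float(v) for v in res.x])
    bse = _approximate_bse(residuals, res.x, data.size)
    return FitResult(
        coefficients=coeffs,
        objective_value=float(res.fun),
        n_voxels=int(data.size),
        converged=bool(res.success),
        start=tuple(float(s) for s in start),
        n_iterations=int(res.nit),
        message=str(res.message),
        bse=bse,
    )


def _approximate_bse(residuals, theta: np.ndarray, n: int) -> Optional[np.ndarray]:
    """Gauss–Newton standard errors from a numerical residual Jacobian.

    cov = s^2 (J^T J)^-1 with s^2 = SSR / (n - p).  Returns None when the
    normal matrix is singular or n <= p.
    """
    p = len(theta)
    if n <= p:
        return None
    J = np.empty((n, p))
    r0 = residuals(theta)
    for j in range(p):
        h = 1e-6 * max(abs(theta[j]), 1e-3)
        tp = theta.copy()
        tp[j] += h
        J[:, j] = (residuals(tp) - r0) / h
    try:
        cov = np.linalg.inv(J.T @ J) * (np.dot(r0, r0) / (n - p))
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d < 0):
        return None
    return np.sqrt(d)


def _paired_stats(model_vals: np.ndarray, ref_vals: np.ndarray) -> Tuple[float, float, float]:
    pct = np.abs(model_vals - ref_vals) / ref_vals * 100.0
    return (
        float(np.percentile(pct, 95)),
        float(np.mean(pct)),
        float(np.max(np.abs(model_vals - ref_vals))),
    )


def agreement_stats(
    model_cube: DoseGrid,
    reference: DoseGrid,
    mask: np.ndarray,
) -> AgreementStats:
    """Per-voxel absolute percentage difference of model vs reference.

    Differences are relative to the reference.  Reports the 95th percentile
    and mean of the absolute percentage difference, and the maximum absolute
    difference in dose units.
    """
    mask = np.asarray(mask, bool)
    m = np.asarray(model_cube.values, float)
    d = np.asarray(reference.values, float)
    if m.shape != d.shape or mask.shape != d.shape:
        raise InvalidInputError("model, reference and mask shapes must match")
    m, d = m[mask], d[mask]
    if m.size == 0:
        raise InvalidInputError("mask selects no voxels")
    if np.any(d <= 0):
        raise InvalidInputError("reference dose must be > 0 on every masked voxel")
    p95, mean, mx = _paired_stats(m, d)
    return AgreementStats(p95, mean, mx, int(m.size))


def compare_point_doses(
    predicted: Sequence[Tuple[Sequence[float], float]],
    measured: Sequence[Tuple[Sequence[float], float]],
) -> AgreementStats:
    """Compare predicted vs measured point doses (e.g. model vs TLD chips).

    Both lists pair a point ``(x, y, z)`` in cm with a dose value; they must
    be matched element-wise.  Statistics are relative to the measured
    values; the per-point table is returned for reporting.
    """
    if len(predicted) != len(measured):
        raise InvalidInputError(
            f"point lists must be matched: {len(predicted)} predicted "
            f"vs {len(measured)} measured"
        )
    if len(predicted) == 0:
        raise InvalidInputError("point lists are empty")
    rows = []
    for (p_pt, p_val), (m_pt, m_val) in zip(predicted, measured):
        if not np.allclose(p_pt, m_pt):
            raise InvalidInputError(
                f"point mismatch: predicted at {tuple(p_pt)}, measured at {tuple(m_pt)}"
            )
        if not m_val > 0:
            raise InvalidInputError("measured values must be > 0")
        x, y, z = (float(c) for c in p_pt)
        rows.append(
            {
                "x_cm": x, "y_cm": y, "z_cm": z,
                "r_cm": float(np.sqrt(x * x + y * y + z * z)),
                "predicted": float(p_val),
                "measured": float(m_val),
                "abs_diff": abs(float(p_val) - float(m_val)),
                "abs_pct_diff": abs(float(p_val) - float(m_val)) / float(m_val) * 100.0,
            }
        )
    table = pd.DataFrame(rows)
    p95, mean, mx = _paired_stats(
        table["predicted"].to_numpy(), table["measured"].to_numpy()
    )
    return AgreementStats(p95, mean, mx, len(table), per_point=table)
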