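"""Closed-form out-of-field photon dose model and its correction factors.

The model estimates the peripheral photon dose (PPD) per monitor unit at a
point ``(x, y, z)`` given in a patient coordinate frame with the origin at
the treatment isocenter: ``x`` anterior–posterior, ``y`` left–right, ``z``
caudal–cranial, all in cm.  With ``r = sqrt(x^2 + y^2 + z^2)``:

.. math::

    \\mathrm{PPD}(x,y,z) =
    \\begin{cases}
        \\epsilon \\, F \\, (A_1 - A_2 |z|) \\, e^{-A_3 r} / r^2
            + (L_u - L_r), & r \\le 40\\,\\mathrm{cm} \\\\
        L_u, & r > 40\\,\\mathrm{cm}
    \\end{cases}

in mGy/MU.  The scatter branch captures patient and collimator scatter
falling off with distance; beyond 40 cm from the isocenter only head leakage
``L_u`` remains.  The model applies *outside* the 5 % isodose surface only —
inside it the treatment planning system is the authority.

Two treatment-specific correction factors rescale the calibrated reference:
``epsilon = E_U / E_R`` (treatment efficiency, prescribed isocenter dose per
MU, relative to the reference plan) and ``F = F_U / F_R`` (field area from
the 50 % isodose, relative to the reference field area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, OutOfValidityError

__all__ = [
    "ModelCoefficients",
    "TreatmentParameters",
    "ReferenceConstants",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_REFERENCE",
    "treatment_efficiency",
    "efficiency_factor",
    "field_factor",
    "ppd_at_point",
    "ppd_at_points",
    "absolute_dose",
    "normalize_to_isocenter_dose",
]

#: Radius below which the point-source-like scatter term is not trusted.
#: The equation diverges as r -> 0, but it is only ever evaluated outside
#: the 5 % isodose; queries closer than this raise OutOfValidityError.
R_MIN_CM = 1.0


@dataclass(frozen=True)
class ModelCoefficients:
    """The three fitted constants of the calibrated dose equation.

    Attributes
    ----------
    A1 : float
        Scatter amplitude, mGy·cm²/MU.
    A2 : float
        Craniocaudal gradient, mGy·cm/MU.
    A3 : float
        Effective attenuation coefficient, cm⁻¹.
    """

    A1: float = 37.890
    A2: float = 0.679
    A3: float = 0.007

    def __post_init__(self) -> None:
        if not self.A1 > 0:
            raise InvalidParameterError(f"A1 must be > 0, got {self.A1}")
        if self.A2 < 0 or self.A3 < 0:
            raise InvalidParameterError(
                f"A2 and A3 must be >= 0, got A2={self.A2}, A3={self.A3}"
            )
        # |z| <= r <= 40 cm wherever the scatter branch applies, so this
        # guarantees the scatter bracket stays positive on the whole domain.
        if not self.A1 - self.A2 * 40.0 > 0:
            raise InvalidParameterError(
                f"A1 - 40*A2 must be > 0 (got {self.A1 - self.A2 * 40.0}); "
                "the scatter bracket would go negative inside the validity region"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.A3], dtype=float)


@dataclass(frozen=True)
class ReferenceConstants:
    """Constants of the reference treatment the model was calibrated on.

    ``E_R`` is the reference treatment efficiency (2000 mGy at the isocenter
    in 278 MU), ``F_R`` the reference field area from the mean 50 %-isodose
    area of the coronal and sagittal planes, ``L_r`` the reference head
    leakage.  ``r_cut`` is the radius beyond which only leakage contributes
    and ``isodose_exclusion`` the in-field isodose fraction outside of which
    the model is valid.
    """

    E_R: float = 2000.0 / 278.0  # mGy/MU, prints as 7.2
    F_R: float = 149.2  # cm^2
    L_r: float = 0.001  # mGy/MU
    r_cut: float = 40.0  # cm
    isodose_exclusion: float = 0.05

    def __post_init__(self) -> None:
        for name in ("E_R", "F_R", "L_r", "r_cut"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0.0 < self.isodose_exclusion < 1.0:
            raise InvalidParameterError("isodose_exclusion must lie in (0, 1)")


@dataclass(frozen=True)
class TreatmentParameters:
    """Plan-level inputs for the user's treatment.

    Attributes
    ----------
    prescription : float
        Prescribed isocenter dose for the whole treatment, mGy.
    total_MU : float
        Total monitor units delivering that prescription.
    F_U : float
        User field area (mean 50 %-isodose area), cm².
    L_u : float
        User linac leakage, mGy/MU.  Defaults to the reference value so the
        ``L_u - L_r`` term vanishes when no measurement is available.
    """

    prescription: float = 2000.0
    total_MU: float = 278.0
    F_U: float = 149.2
    L_u: float = 0.001

    def __post_init__(self) -> None:
        if not self.prescription > 0:
            raise InvalidParameterError("prescription must be > 0 mGy")
        if not self.total_MU >= 1:
            raise InvalidParameterError("total_MU must be >= 1 MU")
        if not self.F_U > 0:
            raise InvalidParameterError("F_U must be > 0 cm^2")
        if self.L_u < 0:
            raise InvalidParameterError("L_u must be >= 0 mGy/MU")

    @property
    def E_U(self) -> float:
        """User treatment efficiency, mGy/MU."""
        return treatment_efficiency(self.prescription, self.total_MU)


DEFAULT_COEFFICIENTS = ModelCoefficients()
DEFAULT_REFERENCE = ReferenceConstants()


def treatment_efficiency(prescription: float, total_MU: float) -> float:
    """Treatment efficiency E = prescribed isocenter dose per MU, mGy/MU.

    E.g. a 2 Gy fraction plan delivering 2000 mGy in 278 MU has
    E = 7.194 mGy/MU (usually quoted rounded as 7.2).
    """
    if not prescription > 0:
        raise InvalidParameterError("prescription must be > 0 mGy")
    if not total_MU > 0:
        raise InvalidParameterError("total_MU must be > 0 MU")
    return prescription / total_MU


def efficiency_factor(E_U: float, E_R: float) -> float:
    """MU correction factor epsilon = E_U / E_R (dimensionless)."""
    if not (E_U > 0 and E_R > 0):
        raise InvalidParameterError("efficiencies must be > 0 mGy/MU")
    return E_U / E_R


def field_factor(F_U: float, F_R: float) -> float:
    """Field-size correction factor F = F_U / F_R (dimensionless)."""
    if not (F_U > 0 and F_R > 0):
        raise InvalidParameterError("field areas must be > 0 cm^2")
    return F_U / F_R


def _scatter_dose(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    eps: float,
    F: float,
    L_u: float,
    L_r: float,
    A1: float,
    A2: float,
    A3: float,
    r_cut: float,
) -> np.ndarray:
    """Vectorised piecewise evaluation; NaN below the r_min guard."""
    r2 = x * x + y * y + z * z
    r = np.sqrt(r2)
    with np.errstate(divide="ignore", invalid="ignore"):
        scatter = eps * F * (A1 - A2 * np.abs(z)) * np.exp(-A3 * r) / r2
    out = np.where(r <= r_cut, np.maximum(scatter + (L_u - L_r), 0.0), L_u)
    return np.where(r < R_MIN_CM, np.nan, out)


def ppd_at_points(
    x,
    y,
    z,
    params: TreatmentParameters = TreatmentParameters(),
    ref: ReferenceConstants = DEFAULT_REFERENCE,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> np.ndarray:
    """Vectorised peripheral dose per MU at isocenter-frame points, mGy/MU.

    Points closer than the ``R_MIN_CM`` validity guard yield NaN (callers
    that require a hard failure should use :func:`ppd_at_point`).
    """
    x, y, z = np.asarray(x, float), np.asarray(y, float), np.asarray(z, float)
    eps = efficiency_factor(params.E_U, ref.E_R)
    F = field_factor(params.F_U, ref.F_R)
    return _scatter_dose(
        x, y, z, eps, F, params.L_u, ref.L_r,
        coeffs.A1, coeffs.A2, coeffs.A3, ref.r_cut,
    )


def ppd_at_point(
    x: float,
    y: float,
    z: float,
    params: TreatmentParameters = TreatmentParameters(),
    ref: ReferenceConstants = DEFAULT_REFERENCE,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Peripheral photon dose per MU at one point, mGy/MU.

    Raises
    ------
    OutOfValidityError
        If the point lies closer than ``R_MIN_CM`` to the isocenter.  The
        caller is responsible for only querying outside the 5 % isodose;
        the radial guard catches the worst misuse (the scatter term
        diverges at the origin).
    """
    r = math.sqrt(x * x + y * y + z * z)
    if r < R_MIN_CM:
        raise OutOfValidityError(
            f"point at r={r:.3g} cm is inside the {R_MIN_CM:g} cm validity "
            "guard; the model is undefined near the isocenter"
        )
    value = ppd_at_points(x, y, z, params, ref, coeffs)
    return float(value)


def absolute_dose(ppd_per_MU: float, total_MU: float):
    """Absolute peripheral dose for the whole treatment, mGy."""
    if not total_MU > 0:
        raise InvalidParameterError("total_MU must be > 0 MU")
    return np.asarray(ppd_per_MU, float) * total_MU


def normalize_to_isocenter_dose(ppd_per_MU, total_MU: float, prescription: float):
    """Express dose per MU as peripheral dose (mGy) per isocenter dose (Gy).

    This is the mGy/Gy scale customary for reporting out-of-field doses:
    total peripheral dose divided by the prescription in Gy.
    """
    if not prescription > 0:
        raise InvalidParameterError("prescription must be > 0 mGy")
    if not total_MU > 0:
        raise InvalidParameterError("total_MU must be > 0 MU")
    return np.asarray(ppd_per_MU, float) * total_MU / (prescription / 1000.0)
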