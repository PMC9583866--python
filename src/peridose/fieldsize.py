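"""Field-area extraction from a 3D dose distribution.

The model's field-size input ``F_U`` is defined as the average of the areas
inside the 50 % isodose on the coronal and sagittal planes through the
isocenter.  Areas are measured by pixel counting with an inclusive
threshold; no sub-pixel contouring is attempted, so the result carries a
discretization error of order one pixel row.

An alternative 1D recipe is provided (``method="profile"``): the field area
as the product of the full widths at half maximum of the two in-plane dose
profiles through the isocenter, averaged over both planes.  The area method
is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .grid import DoseGrid, IsocenterFrame, interpolate_at_point

__all__ = ["PlaneSpec", "plane_isodose_area", "field_area", "profile_fwhm"]

#: model-axis pairs spanned by each named plane (0=AP, 1=LR, 2=craniocaudal)
_PLANE_AXES = {"coronal": (1, 2), "sagittal": (0, 2)}


@dataclass(frozen=True)
class PlaneSpec:
    """A coronal or sagittal plane through a given position (cm, model frame)."""

    orientation: str
    position: float = 0.0

    def __post_init__(self) -> None:
        if self.orientation not in _PLANE_AXES:
            raise InvalidInputError(
                f"orientation must be 'coronal' or 'sagittal', got {self.orientation!r}"
            )


def _plane_slice(dose: DoseGrid, frame: IsocenterFrame, plane: PlaneSpec):
    """Extract the voxel slab nearest the plane position.

    Returns the 2D dose array, the pixel area (cm²) and the two (grid axis,
    sign, coords) in-plane descriptors.  Nearest-slab extraction has a known
    half-voxel positioning bias; no inter-slice interpolation is done.
    """
    in_plane = _PLANE_AXES[plane.orientation]
    normal_model_axis = ({0, 1, 2} - set(in_plane)).pop()
    g_norm, sign = frame.grid_axis(normal_model_axis)
    iso = np.asarray(frame.isocenter, float)
    # plane.position is a model-frame coordinate along the normal axis
    target = iso[g_norm] + sign * plane.position
    coords = dose.axis_coords(g_norm)
    if target < coords.min() - dose.spacing[g_norm] / 2 or target > coords.max() + dose.spacing[g_norm] / 2:
        raise InvalidInputError(
            f"{plane.orientation} plane at {plane.position} cm lies outside the grid"
        )
    k = int(np.argmin(np.abs(coords - target)))
    slab = np.take(np.asarray(dose.values, float), k, axis=g_norm)
    other = [a for a in range(3) if a != g_norm]
    pixel_area = float(dose.spacing[other[0]] * dose.spacing[other[1]])
    return slab, pixel_area, other


def plane_isodose_area(
    dose: DoseGrid,
    frame: IsocenterFrame,
    plane: PlaneSpec,
    fraction: float = 0.5,
) -> float:
    """Area (cm²) inside the ``fraction`` isodose on the given plane.

    The threshold is relative to the dose trilinearly interpolated at the
    isocenter.  Counts plane pixels with dose >= fraction * isocenter dose.
    """
    iso_dose = interpolate_at_point(dose, frame.isocenter)
    if not iso_dose > 0:
        raise InvalidInputError("dose at the isocenter must be > 0")
    slab, pixel_area, _ = _plane_slice(dose, frame, plane)
    n = int(np.count_nonzero(slab >= fraction * iso_dose))
    if n == 0:
        warnings.warn(
            f"no {plane.orientation} pixels reach {fraction:.0%} of the isocenter "
            "dose; returning 0 cm^2",
            stacklevel=2,
        )
    return n * pixel_area


def profile_fwhm(values: np.ndarray, coords: np.ndarray, half_level: float) -> float:
    """Full width (cm) of a 1D profile at ``half_level``, by linear interpolation.

    Finds the outermost crossings around the profile maximum.
    """
    above = values >= half_level
    if not above.any():
        return 0.0
    idx = np.nonzero(above)[0]
    lo, hi = idx[0], idx[-1]
    left = coords[lo]
    if lo > 0:
        f = (half_level - values[lo - 1]) / (values[lo] - values[lo - 1])
        left = coords[lo - 1] + f * (coords[lo] - coords[lo - 1])
    right = coords[hi]
    if hi < len(values) - 1:
        f = (half_level - values[hi]) / (values[hi + 1] - values[hi])
        right = coords[hi] + f * (coords[hi + 1] - coords[hi])
    return float(right - left)


def _plane_profile_area(
    dose: DoseGrid, frame: IsocenterFrame, plane: PlaneSpec, fraction: float
) -> float:
    """Product of the 50 % full widths of the two in-plane profiles (cm²)."""
    iso_dose = interpolate_at_point(dose, frame.isocenter)
    slab, _, other = _plane_slice(dose, frame, plane)
    iso_idx = np.rint(
        (np.asarray(frame.isocenter, float) - dose.origin) / dose.spacing
    ).astype(int)
    widths = []
    for ax_pos, ax in enumerate(other):
        line_index = iso_idx[other[1 - ax_pos]]
        profile = np.take(slab, line_index, axis=1 - ax_pos)
        widths.append(profile_fwhm(profile, dose.axis_coords(ax), fraction * iso_dose))
    return widths[0] * widths[1]


def field_area(
    dose: DoseGrid,
    frame: IsocenterFrame,
    fraction: float = 0.5,
    method: str = "area",
) -> float:
    """The field-size parameter F_U (cm²) from a 3D dose distribution.

    Arithmetic mean over the coronal and sagittal planes through the
    isocenter of either the in-plane 50 %-isodose area (``method="area"``,
    default) or the product of the in-plane profile widths at 50 %
    (``method="profile"``).
    """
    planes = [PlaneSpec("coronal"), PlaneSpec("sagittal")]
    if method == "area":
        areas = [plane_isodose_area(dose, frame, p, fraction) for p in planes]
    elif method == "profile":
        areas = [_plane_profile_area(dose, frame, p, fraction) for p in planes]
    else:
        raise InvalidInputError(f"unknown field-area method {method!r}")
    return float(np.mean(areas))
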