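"""Voxel dose grids, the isocenter coordinate frame and whole-grid dose cubes.

A :class:`DoseGrid` is a rectilinear scalar volume with uniform spacing per
axis (cm).  An :class:`IsocenterFrame` states where the treatment isocenter
sits in the grid's physical coordinates and which (signed) grid axis plays
each anatomical role: model x = anterior–posterior, y = left–right,
z = caudal–cranial.  All model mathematics happens in that isocenter-origin
frame, in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    ModelCoefficients,
    ReferenceConstants,
    TreatmentParameters,
    R_MIN_CM,
    ppd_at_points,
)
from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "DoseGrid",
    "IsocenterFrame",
    "voxel_coords_in_model_frame",
    "compute_ppd_cube",
    "in_field_mask",
    "body_interior_mask",
]


@dataclass
class DoseGrid:
    """A 3D scalar dose (or label) volume with physical geometry.

    Attributes
    ----------
    values : ndarray
        Shape ``dims``; indexed ``[i, j, k]`` along grid axes 0, 1, 2.
    spacing : ndarray of 3 floats
        Voxel size per axis, cm.
    origin : ndarray of 3 floats
        Physical position of the center of voxel ``(0, 0, 0)``, cm.
    units : str
        Dose unit tracked with the data: ``"mGy/MU"``, ``"mGy"``,
        ``"mGy/Gy"`` — or ``"label"`` / ``"mask"`` for segmentations.
    rel_error : ndarray, optional
        Per-voxel relative (fractional) statistical error, same shape.
    valid : ndarray of bool, optional
        Per-voxel validity mask; ``False`` marks not-computed (sentinel NaN)
        voxels, e.g. in-field positions a peripheral-dose cube skips.
    """

    values: np.ndarray
    spacing: Sequence[float] = (1.0, 1.0, 1.0)
    origin: Sequence[float] = (0.0, 0.0, 0.0)
    units: str = "mGy/MU"
    rel_error: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise InvalidInputError(
                f"values must be a 3D array with dims >= 1, got shape {self.values.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise InvalidInputError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.origin.shape != (3,):
            raise InvalidInputError("origin must have 3 components")
        if self.rel_error is not None:
            self.rel_error = np.asarray(self.rel_error, dtype=float)
            if self.rel_error.shape != self.values.shape:
                raise InvalidInputError("rel_error shape must match values")
            if np.any(self.rel_error < 0):
                raise InvalidInputError("rel_error must be >= 0")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise InvalidInputError("valid mask shape must match values")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, cm³."""
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (cm) of voxel centers along one grid axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def physical_to_index(self, point: Sequence[float]) -> np.ndarray:
        """Continuous (fractional) voxel index of a physical point."""
        return (np.asarray(point, float) - self.origin) / self.spacing

    def contains_point(self, point: Sequence[float]) -> bool:
        idx = self.physical_to_index(point)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.dims) - 0.5))

    def like(self, values: np.ndarray, units: Optional[str] = None, **kw) -> "DoseGrid":
        """A new grid with this geometry and different values."""
        return DoseGrid(
            values=values,
            spacing=self.spacing.copy(),
            origin=self.origin.copy(),
            units=units if units is not None else self.units,
            **kw,
        )


@dataclass(frozen=True)
class IsocenterFrame:
    """Mapping from grid coordinates to the model's isocenter-origin frame.

    ``axis_map`` is a signed permutation written with 1-based grid axes:
    entry ``m`` names the grid axis (and sign) that supplies model axis ``m``.
    ``(1, 2, 3)`` is the identity (grid axis 0 is anterior–posterior, 1 is
    left–right, 2 is caudal–cranial); ``(1, 2, -3)`` flips the craniocaudal
    direction.
    """

    isocenter: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_map: Tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self) -> None:
        if sorted(abs(a) for a in self.axis_map) != [1, 2, 3]:
            raise ConfigurationError(
                f"axis_map must be a signed permutation of (1, 2, 3), got {self.axis_map}"
            )

    def grid_axis(self, model_axis: int) -> Tuple[int, int]:
        """(grid axis, sign) supplying the given model axis (0=AP, 1=LR, 2=CC)."""
        a = self.axis_map[model_axis]
        return abs(a) - 1, (1 if a > 0 else -1)


def voxel_coords_in_model_frame(
    grid: DoseGrid, frame: IsocenterFrame
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel (x, y, z) model-frame coordinates in cm, each shaped like the grid.

    Voxel centers are translated so the isocenter is at the origin, then the
    axes are permuted and signed according to ``frame.axis_map``.
    """
    iso = np.asarray(frame.isocenter, float)
    offsets = [grid.axis_coords(a) - iso[a] for a in range(3)]
    coords = []
    for m in range(3):
        g, sign = frame.grid_axis(m)
        shape = [1, 1, 1]
        shape[g] = grid.dims[g]
        coords.append(
            np.broadcast_to((sign * offsets[g]).reshape(shape), grid.dims)
        )
    return coords[0], coords[1], coords[2]


def compute_ppd_cube(
    grid: DoseGrid,
    frame: IsocenterFrame,
    params: TreatmentParameters = TreatmentParameters(),
    ref: ReferenceConstants = ReferenceConstants(),
    coeffs: ModelCoefficients = ModelCoefficients(),
    exclusion_mask: Optional[np.ndarray] = None,
) -> DoseGrid:
    """Evaluate the peripheral dose model at every voxel center, mGy/MU.

    Excluded voxels (the in-field ``exclusion_mask`` and anything inside
    the radial validity guard) carry NaN and are flagged ``False`` in the
    returned grid's ``valid`` mask; downstream statistics and DVHs must skip
    them rather than treat them as zero dose.
    """
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, bool)
        if exclusion_mask.shape != grid.dims:
            raise InvalidInputError("exclusion_mask dims must match the grid")
    x, y, z = voxel_coords_in_model_frame(grid, frame)
    values = ppd_at_points(x, y, z, params, ref, coeffs)
    valid = np.isfinite(values)
    if exclusion_mask is not None:
        valid &= ~exclusion_mask
    values = np.where(valid, values, np.nan)
    return grid.like(values, units="mGy/MU", valid=valid)


def interpolate_at_point(grid: DoseGrid, point: Sequence[float]) -> float:
    """Trilinear interpolation of the grid values at a physical point (cm)."""
    idx = grid.physical_to_index(point)
    if not grid.contains_point(point):
        raise InvalidInputError(f"point {tuple(point)} cm lies outside the grid")
    value = ndimage.map_coordinates(
        np.asarray(grid.values, float), idx.reshape(3, 1), order=1, mode="nearest"
    )
    return float(value[0])


def in_field_mask(
    tps_dose: DoseGrid,
    frame: IsocenterFrame,
    fraction: float = 0.05,
) -> np.ndarray:
    """Voxels at or above ``fraction`` of the isocenter dose (the in-field region).

    The reference dose is the trilinear interpolation of the cube at the
    isocenter position — the isocenter rarely coincides with a voxel center.
    """
    iso_dose = interpolate_at_point(tps_dose, frame.isocenter)
    if not iso_dose > 0:
        raise InvalidInputError(
            f"dose interpolated at the isocenter must be > 0, got {iso_dose}"
        )
    return np.asarray(tps_dose.values, float) >= fraction * iso_dose


def body_interior_mask(body_mask: np.ndarray) -> np.ndarray:
    """Erode the body mask by one voxel (6-connectivity).

    Removes the one-voxel surface shell, where electron contamination makes
    the photon-only model unreliable.
    """
    body_mask = np.asarray(body_mask, bool)
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(body_mask, structure=structure, border_value=0)
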