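"""Synthetic phantoms, reference dose cubes and pseudo-dosimeter point sets.

These generators stand in for the data the model is calibrated and
validated against in practice — an anthropomorphic voxel phantom, a Monte
Carlo reference dose cube and scattered in-phantom point dosimeters — so
every pipeline stage is testable end to end.

The phantom is a trunk-like ellipsoidal body with a few ellipsoidal organ
masks.  The reference dose cube is the analytical model itself evaluated
per voxel, optionally perturbed with multiplicative Gaussian noise
(mirroring the relative-error structure of Monte Carlo dose files) and
augmented with an in-field Gaussian high-dose blob so that a 5 % isodose
region exists to exclude.  Default study conditions mirror the reference
plan: 2 Gy at the isocenter in 278 MU, reference field area, leakage
0.001 mGy/MU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ModelCoefficients,
    ReferenceConstants,
    TreatmentParameters,
    R_MIN_CM,
    ppd_at_points,
)
from .exceptions import InvalidInputError
from .grid import DoseGrid, IsocenterFrame, compute_ppd_cube, voxel_coords_in_model_frame

__all__ = [
    "Ellipsoid",
    "GaussianBlob",
    "PhantomSpec",
    "generate_phantom",
    "generate_reference_dose",
    "generate_tld_points",
]


@dataclass(frozen=True)
class Ellipsoid:
    """An axis-aligned ellipsoid: center (cm, grid physical coords) + semiaxes."""

    center: Tuple[float, float, float]
    semiaxes: Tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise InvalidInputError("ellipsoid semiaxes must be > 0")

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semiaxes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semiaxes))


@dataclass(frozen=True)
class GaussianBlob:
    """An isotropic Gaussian in-field dose component centred at the isocenter.

    ``amplitude`` is the peak dose per MU (mGy/MU) at the isocenter;
    ``sigma`` the standard deviation in cm.  The default amplitude matches
    the reference treatment efficiency (7.2 mGy/MU at the isocenter) so the
    blob's 5 % isodose encloses an in-field region to exclude.  The default
    sigma is deliberately narrow: real in-field dose falls off over a
    penumbra of millimetres, so the stand-in's tail must be negligible just
    outside its own 5 % isodose.
    """

    amplitude: float = 2000.0 / 278.0
    sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.sigma <= 0:
            raise InvalidInputError("blob amplitude and sigma must be > 0")


@dataclass
class PhantomSpec:
    """Specification of a synthetic voxel phantom.

    The default geometry is a trunk-sized body ellipsoid (roughly 20 cm AP ×
    30 cm LR semiaxes are half-widths, trunk 70 cm long) on a 2 cm isotropic
    grid spanning the body, with a handful of ellipsoidal organs.  The
    isocenter sits mid-body, as for an abdominal treatment.
    """

    body: Ellipsoid = field(
        default_factory=lambda: Ellipsoid((0.0, 0.0, 0.0), (10.0, 15.0, 35.0))
    )
    organs: Dict[str, Ellipsoid] = field(
        default_factory=lambda: {
            "thyroid": Ellipsoid((0.0, 0.0, 25.0), (2.0, 3.0, 2.0)),
            "lung_L": Ellipsoid((0.0, 6.0, 14.0), (5.0, 5.0, 9.0)),
            "bladder": Ellipsoid((0.0, 0.0, -16.0), (4.0, 4.0, 3.0)),
            "testes": Ellipsoid((0.0, 0.0, -26.0), (2.0, 3.0, 2.0)),
        }
    )
    dims: Tuple[int, int, int] = (13, 17, 37)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: Optional[Tuple[float, float, float]] = None  # default: grid centred on body
    isocenter: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_map: Tuple[int, int, int] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.origin is None:
            c = np.asarray(self.body.center, float)
            self.origin = tuple(
                c - np.asarray(self.spacing) * (np.asarray(self.dims) - 1) / 2.0
            )

    @property
    def frame(self) -> IsocenterFrame:
        return IsocenterFrame(isocenter=self.isocenter, axis_map=self.axis_map)

    def empty_grid(self, units: str = "mGy/MU") -> DoseGrid:
        return DoseGrid(
            values=np.zeros(self.dims),
            spacing=self.spacing,
            origin=self.origin,
            units=units,
        )


def generate_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, DoseGrid, Dict[int, str]]:
    """Voxelise the phantom: body mask, organ label volume and name table.

    Deterministic for a given spec.  Organ labels are 1..n in the spec's
    organ order and disjoint (later organs never overwrite earlier ones).
    """
    grid = spec.empty_grid(units="label")
    xs = [grid.axis_coords(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    body = spec.body.contains(X, Y, Z)
    labels = np.zeros(spec.dims, dtype=np.int16)
    names: Dict[int, str] = {}
    for i, (name, organ) in enumerate(spec.organs.items(), start=1):
        inside = organ.contains(X, Y, Z)
        if not np.all(body[inside]) or not inside.any():
            raise InvalidInputError(
                f"organ {name!r} is not fully inside the body on this grid"
            )
        labels[inside & (labels == 0)] = i
        names[i] = name
    return body, grid.like(labels, units="label"), names


def generate_reference_dose(
    spec: PhantomSpec,
    coeffs: ModelCoefficients = ModelCoefficients(),
    params: TreatmentParameters = TreatmentParameters(),
    ref: ReferenceConstants = ReferenceConstants(),
    noise_cv: float = 0.05,
    blob: Optional[GaussianBlob] = GaussianBlob(),
    seed: Optional[int] = None,
) -> DoseGrid:
    """A synthetic reference dose cube (mGy/MU) emulating a MC simulation.

    Per voxel: the analytical model value, times ``1 + noise_cv * N(0, 1)``
    (multiplicative noise — MC uncertainty is relative), plus the in-field
    Gaussian blob.  The grid's ``rel_error`` array is set to ``noise_cv``.
    Voxels inside the radial validity guard take the blob dose only.
    """
    if noise_cv < 0:
        raise InvalidInputError("noise_cv must be >= 0")
    grid = spec.empty_grid()
    frame = spec.frame
    x, y, z = voxel_coords_in_model_frame(grid, frame)
    values = np.asarray(ppd_at_points(x, y, z, params, ref, coeffs))
    values = np.nan_to_num(values, nan=0.0)  # inside r_min: model undefined
    if noise_cv > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        values = values * (1.0 + noise_cv * rng.standard_normal(values.shape))
        values = np.maximum(values, 0.0)
    if blob is not None:
        r2 = x * x + y * y + z * z
        values = values + blob.amplitude * np.exp(-r2 / (2.0 * blob.sigma**2))
    return grid.like(
        values,
        units="mGy/MU",
        rel_error=np.full(spec.dims, float(noise_cv)),
    )


def generate_tld_points(
    n: int,
    r_range: Tuple[float, float] = (8.0, 45.0),
    coeffs: ModelCoefficients = ModelCoefficients(),
    params: TreatmentParameters = TreatmentParameters(),
    ref: ReferenceConstants = ReferenceConstants(),
    noise_cv: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Scattered point-dosimeter positions with true and noisy dose values.

    Points are drawn uniformly (per volume) in the spherical annulus
    ``r_range`` (cm) around the isocenter — emulating dosimeter chips
    scattered through a phantom's organs, outside the in-field region.
    Columns: x, y, z (cm), true (mGy/MU), measured (true × multiplicative
    Gaussian noise).
    """
    r_lo, r_hi = r_range
    if not (0 < r_lo < r_hi):
        raise InvalidInputError("r_range must satisfy 0 < r_lo < r_hi")
    if r_lo < R_MIN_CM:
        raise InvalidInputError(f"r_lo must be >= the {R_MIN_CM:g} cm validity guard")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)  # uniform per volume
    direction = rng.standard_normal((n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    pts = direction * r[:, None]
    true = np.asarray(ppd_at_points(pts[:, 0], pts[:, 1], pts[:, 2], params, ref, coeffs))
    measured = true * np.maximum(1.0 + noise_cv * rng.standard_normal(n), 0.0)
    return pd.DataFrame(
        {
            "x_cm": pts[:, 0],
            "y_cm": pts[:, 1],
            "z_cm": pts[:, 2],
            "r_cm": r,
            "true": true,
            "measured": measured,
        }
    )
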