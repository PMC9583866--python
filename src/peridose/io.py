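"""Readers and writers for the volume formats and configs the tool touches.

Supported volumes:

* EGSnrc/DOSXYZnrc ``.3ddose`` text files (dose + relative-error arrays);
* NIfTI (``.nii`` / ``.nii.gz``) via nibabel;
* MetaImage (``.mha`` / ``.mhd``) and DICOM series directories via SimpleITK;
* single-file DICOM RT-Dose via pydicom (grid scaling applied).

All geometry is normalised to cm internally (DICOM, NIfTI and MetaImage
speak mm); ``.3ddose`` boundaries are taken as cm by the EGSnrc convention,
with an override for nonstandard exports.  Only axis-aligned geometries are
accepted; oblique volumes are rejected rather than silently resampled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from .core import ModelCoefficients, ReferenceConstants
from .exceptions import FormatError, InvalidInputError
from .grid import DoseGrid

__all__ = [
    "read_3ddose",
    "write_3ddose",
    "read_volume",
    "write_volume",
    "read_coefficients_config",
    "write_coefficients_config",
    "read_plan_summary",
    "PlanSummary",
    "read_label_volume",
    "write_label_volume",
]

MM_PER_CM = 10.0


# ---------------------------------------------------------------------------
# .3ddose
# ---------------------------------------------------------------------------

def _centers_and_spacing(bounds: np.ndarray, axis: str) -> Tuple[float, float]:
    """Origin (first center) and uniform spacing from voxel boundaries."""
    if np.any(np.diff(bounds) <= 0):
        raise FormatError(f"{axis} voxel boundaries are not strictly increasing")
    widths = np.diff(bounds)
    if widths.size > 1 and not np.allclose(widths, widths[0], rtol=1e-6):
        raise FormatError(
            f"non-uniform {axis} voxel widths are not supported "
            f"(min {widths.min():g}, max {widths.max():g})"
        )
    return float((bounds[0] + bounds[1]) / 2.0), float(widths[0])


def read_3ddose(path, units_mm: bool = False) -> DoseGrid:
    """Read a DOSXYZnrc ``.3ddose`` file into a :class:`DoseGrid`.

    Layout: voxel counts ``nx ny nz``; then the ``nx+1``, ``ny+1`` and
    ``nz+1`` voxel boundary coordinates; then ``nx*ny*nz`` dose values in
    x-fastest order; then the same count of relative errors.  Boundaries are
    treated as cm (EGSnrc convention) unless ``units_mm`` is set.
    """
    path = Path(path)
    tokens = path.read_text().split()
    if len(tokens) < 3:
        raise FormatError(f"{path}: missing voxel-count record")
    try:
        nx, ny, nz = (int(float(t)) for t in tokens[:3])
    except ValueError as exc:
        raise FormatError(f"{path}: bad voxel-count record {tokens[:3]}") from exc
    if min(nx, ny, nz) < 1:
        raise FormatError(f"{path}: voxel counts must be >= 1, got {(nx, ny, nz)}")
    n = nx * ny * nz
    expected = 3 + (nx + 1) + (ny + 1) + (nz + 1) + 2 * n
    if len(tokens) < expected:
        raise FormatError(
            f"{path}: truncated file, expected {expected} tokens, found {len(tokens)}"
        )
    try:
        values = np.array([float(t) for t in tokens[3:expected]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric token in data records") from exc
    pos = 0
    bounds = []
    for count in (nx + 1, ny + 1, nz + 1):
        bounds.append(values[pos : pos + count])
        pos += count
    dose = values[pos : pos + n]
    rel_error = values[pos + n : pos + 2 * n]

    scale = 1.0 / MM_PER_CM if units_mm else 1.0
    origin, spacing = zip(
        *(_centers_and_spacing(b * scale, ax) for b, ax in zip(bounds, "xyz"))
    )
    # file order is x-fastest: reshape as (z, y, x) then transpose to [x, y, z]
    cube = dose.reshape(nz, ny, nx).transpose(2, 1, 0)
    err = rel_error.reshape(nz, ny, nx).transpose(2, 1, 0)
    return DoseGrid(
        values=cube,
        spacing=spacing,
        origin=origin,
        units="mGy/MU",
        rel_error=err,
    )


def write_3ddose(grid: DoseGrid, path) -> None:
    """Write a :class:`DoseGrid` in ``.3ddose`` layout (boundaries in cm).

    The relative-error record is written as zeros when the grid carries
    none.
    """
    path = Path(path)
    nx, ny, nz = grid.dims
    lines = [f"{nx} {ny} {nz}"]
    for axis in range(3):
        edges = grid.origin[axis] + grid.spacing[axis] * (
            np.arange(grid.dims[axis] + 1) - 0.5
        )
        lines.append(" ".join(f"{e:.6f}" for e in edges))
    flat = np.asarray(grid.values, float).transpose(2, 1, 0).ravel()
    lines.append(" ".join(f"{v:.8e}" for v in flat))
    err = grid.rel_error if grid.rel_error is not None else np.zeros(grid.dims)
    flat_err = np.asarray(err, float).transpose(2, 1, 0).ravel()
    lines.append(" ".join(f"{v:.8e}" for v in flat_err))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# NIfTI / MetaImage / DICOM
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> DoseGrid:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    # accept axis-aligned (diagonal up to sign/permutation) affines only
    if np.count_nonzero(np.abs(rot) > 1e-6) != 3:
        raise FormatError(f"{path}: oblique NIfTI orientation is not supported")
    spacing_mm = np.sqrt((rot**2).sum(axis=0))
    return DoseGrid(
        values=np.asarray(img.dataobj),
        spacing=spacing_mm / MM_PER_CM,
        origin=affine[:3, 3] / MM_PER_CM,
        units="unknown",
    )


def _read_sitk(path: Path) -> DoseGrid:
    import SimpleITK as sitk

    if path.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(path))
        if not files:
            raise FormatError(f"{path}: no DICOM series found")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        img = sitk.ReadImage(str(path))
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if np.count_nonzero(np.abs(direction) > 1e-6) != 3:
        raise FormatError(f"{path}: oblique volume orientation is not supported")
    # sitk array is [z, y, x]; transpose to grid order [x, y, z]
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return DoseGrid(
        values=values,
        spacing=np.array(img.GetSpacing()) / MM_PER_CM,
        origin=np.array(img.GetOrigin()) / MM_PER_CM,
        units="unknown",
    )


def _read_rtdose(path: Path) -> DoseGrid:
    import pydicom

    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", "") != "RTDOSE":
        raise FormatError(f"{path}: DICOM file is not an RT-Dose object")
    if not hasattr(ds, "DoseGridScaling"):
        raise FormatError(f"{path}: RT-Dose is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    # pixel_array is [frame(z), row(y), col(x)]
    values = ds.pixel_array.astype(float).transpose(2, 1, 0) * scaling
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if dz.size and not np.allclose(dz, dz[0], rtol=1e-6):
        raise FormatError(f"{path}: non-uniform frame spacing is not supported")
    z_mm = float(dz[0]) if dz.size else 1.0
    origin_mm = np.asarray([float(v) for v in ds.ImagePositionPatient])
    return DoseGrid(
        values=values,
        spacing=np.array([col_mm, row_mm, abs(z_mm)]) / MM_PER_CM,
        origin=origin_mm / MM_PER_CM,
        units="mGy" if getattr(ds, "DoseUnits", "GY") == "GY" else "unknown",
    )


def read_volume(path) -> DoseGrid:
    """Read a volume (dose or labels) and normalise its geometry to cm.

    Dispatches on the path: ``.3ddose`` text, NIfTI, MetaImage, a DICOM
    RT-Dose file, or a DICOM series directory.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".3ddose"):
        return read_3ddose(path)
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith(".dcm"):
        return _read_rtdose(path)
    if path.is_dir() or name.endswith((".mha", ".mhd")):
        return _read_sitk(path)
    raise FormatError(f"{path}: unrecognised volume format")


def write_volume(grid: DoseGrid, path) -> None:
    """Write a grid as NIfTI (mm geometry) or ``.3ddose`` by extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".3ddose"):
        write_3ddose(grid, path)
        return
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(grid.spacing * MM_PER_CM) + [1.0])
        affine[:3, 3] = grid.origin * MM_PER_CM
        nib.save(nib.Nifti1Image(np.asarray(grid.values, np.float64), affine), str(path))
        return
    raise FormatError(f"{path}: unsupported output format")


def read_label_volume(path, names_path=None) -> Tuple[DoseGrid, Dict[int, str]]:
    """Read an integer label volume plus its JSON name-table sidecar.

    The sidecar maps label numbers to organ names; when missing, labels are
    named ``label_<n>``.
    """
    grid = read_volume(path)
    labels = np.unique(np.asarray(grid.values))
    labels = [int(v) for v in labels if v != 0]
    if names_path is not None and Path(names_path).exists():
        raw = json.loads(Path(names_path).read_text())
        names = {int(k): str(v) for k, v in raw.items()}
    else:
        names = {v: f"label_{v}" for v in labels}
    grid.units = "label"
    return grid, names


def write_label_volume(grid: DoseGrid, names: Dict[int, str], path, names_path=None) -> None:
    """Write a label volume and its JSON name table."""
    write_volume(grid.like(np.asarray(grid.values, np.int16), units="label"), path)
    if names_path is None:
        names_path = Path(str(path).split(".nii")[0] + "_names.json")
    Path(names_path).write_text(
        json.dumps({str(k): v for k, v in names.items()}, indent=2) + "\n"
    )


# ---------------------------------------------------------------------------
# key=value coefficients config and plan summary
# ---------------------------------------------------------------------------

_COEFF_KEYS = ("A1", "A2", "A3")
_REF_KEYS = ("E_R", "F_R", "L_r", "r_cut", "isodose_exclusion")


def read_coefficients_config(path) -> Tuple[ModelCoefficients, ReferenceConstants]:
    """Read model coefficients and reference constants from key=value text.

    Keys absent from the file keep their built-in defaults; ``#`` starts a
    comment.
    """
    values: Dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, val = line.partition("=")
        try:
            values[key.strip()] = float(val)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value {val!r}") from exc
    unknown = set(values) - set(_COEFF_KEYS) - set(_REF_KEYS)
    if unknown:
        raise FormatError(f"{path}: unknown keys {sorted(unknown)}")
    coeffs = ModelCoefficients(
        **{k: values[k] for k in _COEFF_KEYS if k in values}
    )
    ref = ReferenceConstants(**{k: values[k] for k in _REF_KEYS if k in values})
    return coeffs, ref


def write_coefficients_config(
    coeffs: ModelCoefficients, ref: ReferenceConstants, path
) -> None:
    """Write coefficients and reference constants as key=value text."""
    lines = ["# peripheral dose model constants"]
    for key in _COEFF_KEYS:
        lines.append(f"{key} = {getattr(coeffs, key)!r}")
    for key in _REF_KEYS:
        lines.append(f"{key} = {getattr(ref, key)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PlanSummary:
    """Plan-level inputs read from a JSON plan file."""

    prescription: float
    total_MU: float
    F_U: Union[float, str] = "derive"
    L_u: Optional[float] = None
    isocenter: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_map: Tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self) -> None:
        if not self.prescription > 0 or not self.total_MU > 0:
            raise InvalidInputError("prescription and total_MU must be > 0")
        if self.F_U != "derive" and not float(self.F_U) > 0:
            raise InvalidInputError("F_U must be > 0 cm^2 or 'derive'")


def read_plan_summary(path) -> PlanSummary:
    """Read a JSON plan summary (prescription mGy, total MU, F_U, isocenter cm)."""
    raw = json.loads(Path(path).read_text())
    try:
        return PlanSummary(
            prescription=float(raw["prescription_mGy"]),
            total_MU=float(raw["total_MU"]),
            F_U=raw.get("F_U_cm2", "derive"),
            L_u=(float(raw["L_u_mGy_per_MU"]) if "L_u_mGy_per_MU" in raw else None),
            isocenter=tuple(float(v) for v in raw.get("isocenter_cm", (0, 0, 0))),
            axis_map=tuple(int(v) for v in raw.get("axis_map", (1, 2, 3))),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: plan summary is missing field {exc}") from exc


def provenance_record(**kwargs) -> Dict:
    """A machine-readable record of inputs and constants for one run."""
    rec = {"tool": "peridose", "version": __version__}
    rec.update(kwargs)
    return rec
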