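"""Cumulative dose–volume histograms for organ masks on a dose cube.

The cumulative DVH reports, for each dose level d, the percentage of the
organ volume receiving at least d.  Peripheral doses are small, so the
default bin width is fine (0.1 mGy).  Voxels flagged invalid in the dose
grid (in-field sentinel NaN) are excluded from the histogram and their
fraction reported, since the model is undefined there and the planning
system covers that region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .exceptions import FormatError, InvalidInputError
from .grid import DoseGrid

__all__ = [
    "OrganMask",
    "DVHCurve",
    "cumulative_dvh",
    "dose_stats",
    "export_dvh_ascii",
    "import_dvh_ascii",
]

DEFAULT_BIN_WIDTH = 0.1  # mGy


@dataclass
class OrganMask:
    """A named boolean voxel mask for one organ."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class DVHCurve:
    """A cumulative dose–volume curve plus summary statistics for one organ.

    ``cumulative_volume[i]`` is the percentage of the organ volume receiving
    at least ``bin_edges[i]`` (left edges, mGy).  ``excluded_fraction`` is
    the fraction of organ voxels that carried no computed dose (in-field
    sentinel) and were left out.
    """

    organ: str
    bin_edges: np.ndarray
    cumulative_volume: np.ndarray
    d_min: float
    d_max: float
    d_mean: float
    bin_width: float
    volume_cm3: float = float("nan")
    excluded_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, float)
        if self.bin_edges.shape != self.cumulative_volume.shape:
            raise InvalidInputError("bin_edges and cumulative_volume must align")


def _valid_organ_doses(dose: DoseGrid, organ: OrganMask) -> Tuple[np.ndarray, float]:
    if organ.mask.shape != dose.dims:
        raise InvalidInputError("organ mask dims must match the dose grid")
    if organ.n_voxels == 0:
        raise InvalidInputError(f"organ {organ.name!r} is empty")
    values = np.asarray(dose.values, float)[organ.mask]
    valid = np.isfinite(values)
    if dose.valid is not None:
        valid &= dose.valid[organ.mask]
    excluded = 1.0 - valid.mean()
    if excluded > 0.10:
        warnings.warn(
            f"{excluded:.0%} of organ {organ.name!r} voxels have no computed "
            "dose (in-field or invalid) and are excluded from the DVH",
            stacklevel=3,
        )
    doses = values[valid]
    if doses.size == 0:
        raise InvalidInputError(
            f"organ {organ.name!r} has no voxels with a computed dose"
        )
    return doses, float(excluded)


def dose_stats(dose: DoseGrid, organ: OrganMask) -> Tuple[float, float, float]:
    """(d_min, d_max, d_mean) over the organ's computed voxels, dose units.

    With uniform voxel spacing the volume-weighted mean is the plain mean.
    """
    doses, _ = _valid_organ_doses(dose, organ)
    return float(doses.min()), float(doses.max()), float(doses.mean())


def cumulative_dvh(
    dose: DoseGrid,
    organ: OrganMask,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DVHCurve:
    """Cumulative DVH of one organ on a dose cube.

    V(d) = 100 × (# organ voxels with dose >= d) / (# organ voxels counted),
    evaluated at the left edge of each bin.  Bins span [0, d_max + one bin],
    so the curve starts at 100 % and reaches 0 % beyond d_max.
    """
    if not bin_width > 0:
        raise InvalidInputError("bin_width must be > 0")
    doses, excluded = _valid_organ_doses(dose, organ)
    d_min, d_max, d_mean = float(doses.min()), float(doses.max()), float(doses.mean())
    n_bins = int(np.floor(d_max / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    volume = 100.0 * (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVHCurve(
        organ=organ.name,
        bin_edges=edges,
        cumulative_volume=volume,
        d_min=d_min,
        d_max=d_max,
        d_mean=d_mean,
        bin_width=bin_width,
        volume_cm3=organ.n_voxels * dose.voxel_volume,
        excluded_fraction=excluded,
    )


def export_dvh_ascii(curve: DVHCurve, path) -> None:
    """Write a DVH as a two-column ASCII table (dose, cumulative volume %).

    Header lines are prefixed with ``#`` and record the organ name, bin
    width and summary doses.  Decimal points are locale-independent.
    """
    path = Path(path)
    lines = [
        f"# organ: {curve.organ}",
        f"# bin_width_mGy: {curve.bin_width!r}",
        f"# d_min_mGy: {curve.d_min!r}",
        f"# d_max_mGy: {curve.d_max!r}",
        f"# d_mean_mGy: {curve.d_mean!r}",
        f"# volume_cm3: {curve.volume_cm3!r}",
        f"# excluded_fraction: {curve.excluded_fraction!r}",
        "# dose_mGy  volume_pct",
    ]
    for d, v in zip(curve.bin_edges, curve.cumulative_volume):
        lines.append(f"{float(d)!r} {float(v)!r}")
    path.write_text("\n".join(lines) + "\n")


def import_dvh_ascii(path) -> DVHCurve:
    """Read a DVH written by :func:`export_dvh_ascii` (exact roundtrip)."""
    path = Path(path)
    meta = {}
    edges, volumes = [], []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        edges.append(float(parts[0]))
        volumes.append(float(parts[1]))
    try:
        return DVHCurve(
            organ=meta.get("organ", ""),
            bin_edges=np.array(edges),
            cumulative_volume=np.array(volumes),
            d_min=float(meta["d_min_mGy"]),
            d_max=float(meta["d_max_mGy"]),
            d_mean=float(meta["d_mean_mGy"]),
            bin_width=float(meta["bin_width_mGy"]),
            volume_cm3=float(meta.get("volume_cm3", "nan")),
            excluded_fraction=float(meta.get("excluded_fraction", "0")),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing DVH header field {exc}") from exc
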