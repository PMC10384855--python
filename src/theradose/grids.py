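"""Voxel grids, scalar volumes and ROI label maps.

Coordinate convention: voxel indices are 0-based and world coordinates are
voxel centers, ``world = origin + index * spacing`` (mm per axis).  Arrays are
indexed ``values[i, j, k]`` with axis order matching ``grid.shape``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import SimpleITK as sitk

#: Unit tags understood by the pipeline.  Every stage checks them before
#: touching the numbers (cheap dimensional analysis).
UNITS = ("Bq/mL", "g/cm3", "Gy/h", "Gy", "1")


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned regular voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels per axis.
    spacing : tuple of float
        Voxel edge length per axis, mm.
    origin : tuple of float
        World position of the center of voxel (0, 0, 0), mm.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (1 mL = 1000 mm³)."""
        return self.voxel_volume_mm3 / 1000.0

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis, mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )


@dataclass
class ScalarVolume:
    """A 3-D scalar field on a :class:`VoxelGrid` with explicit units.

    ``timestamp`` is hours post injection; ``nuclide_tag`` names the
    radionuclide an activity volume refers to.  Both are optional for
    non-activity volumes (density, dose).
    """

    grid: VoxelGrid
    values: np.ndarray
    units: str
    timestamp: float | None = None
    nuclide_tag: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.values.ndim}")
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"array shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        if self.units != "1" and np.any(self.values < 0):
            idx = tuple(int(i) for i in np.argwhere(self.values < 0)[0])
            raise ValueError(f"negative value in {self.units} volume at voxel {idx}")

    def require_units(self, units: str, what: str = "volume") -> None:
        if self.units != units:
            raise ValueError(f"{what} must have units {units!r}, got {self.units!r}")

    def require_timestamp(self) -> float:
        if self.timestamp is None:
            raise ValueError("volume has no timestamp (hours post injection required)")
        return float(self.timestamp)

    def total(self) -> float:
        """Sum of voxel values times voxel volume in mL.

        For a Bq/mL volume this is the total activity in Bq.
        """
        return float(self.values.sum(dtype=np.float64)) * self.grid.voxel_volume_ml

    def with_values(self, values: np.ndarray, **changes) -> "ScalarVolume":
        out = replace(self, values=values)
        for k, v in changes.items():
            setattr(out, k, v)
        return out


@dataclass
class RoiSet:
    """Integer ROI label map plus a label ↔ name mapping.

    Label 0 is reserved for background and never named.
    """

    label_volume: ScalarVolume
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lv = self.label_volume
        if not np.issubdtype(lv.values.dtype, np.integer):
            raise ValueError("label volume must hold integers")
        if lv.units != "1":
            raise ValueError("label volume must be dimensionless ('1')")
        self.names = {int(k): str(v) for k, v in self.names.items()}
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")
        present = set(np.unique(lv.values).tolist())
        missing = [n for lab, n in self.names.items() if lab not in present]
        if missing:
            raise ValueError(f"named ROIs absent from label volume: {missing}")

    @property
    def labels(self) -> dict[str, int]:
        return {v: k for k, v in self.names.items()}

    def mask(self, name: str) -> np.ndarray:
        try:
            label = self.labels[name]
        except KeyError:
            raise KeyError(f"unknown ROI {name!r}; have {sorted(self.labels)}") from None
        return self.label_volume.values == label

    def voxel_count(self, name: str) -> int:
        return int(self.mask(name).sum())


def _to_sitk(vol: ScalarVolume) -> sitk.Image:
    # SimpleITK uses (x, y, z) index order; our arrays are (i, j, k) with the
    # same meaning, so transpose when crossing the boundary.
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(vol.grid.spacing))
    img.SetOrigin(tuple(vol.grid.origin))
    return img


def resample_to_reference(
    vol: ScalarVolume, ref: VoxelGrid, mode: str = "trilinear"
) -> ScalarVolume:
    """Resample ``vol`` onto the reference grid.

    ``mode`` is ``"trilinear"`` for continuous fields or ``"nearest"`` for
    label maps; requesting trilinear interpolation of an integer label volume
    is rejected because it would invent labels.
    """
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"mode must be 'trilinear' or 'nearest', got {mode!r}")
    is_label = np.issubdtype(vol.values.dtype, np.integer)
    if is_label and mode != "nearest":
        raise ValueError("label volumes must be resampled with mode='nearest'")
    if ref == vol.grid:
        return vol.with_values(vol.values.copy())

    interp = sitk.sitkLinear if mode == "trilinear" else sitk.sitkNearestNeighbor
    img = _to_sitk(vol if not is_label else vol.with_values(vol.values.astype(np.int32)))
    out = sitk.Resample(
        img,
        size=[int(n) for n in ref.shape],
        transform=sitk.Transform(),
        interpolator=interp,
        outputOrigin=tuple(ref.origin),
        outputSpacing=tuple(ref.spacing),
        outputDirection=img.GetDirection(),
        defaultPixelValue=0.0,
    )
    arr = sitk.GetArrayFromImage(out).T
    if is_label:
        arr = arr.astype(vol.values.dtype)
    return ScalarVolume(
        grid=ref,
        values=arr,
        units=vol.units,
        timestamp=vol.timestamp,
        nuclide_tag=vol.nuclide_tag,
    )
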