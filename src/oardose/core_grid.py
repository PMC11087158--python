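"""Voxel-grid data model shared by every pipeline stage.

All volumes live on axis-aligned regular grids with a fixed ``(z, y, x)``
index order.  ``spacing`` and ``origin`` are in millimetres; ``origin`` is
the physical position of the centre of voxel ``(0, 0, 0)``.  Dose values
are stored in cGy throughout; unit conversion happens only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "GridHeader",
    "DoseGrid",
    "StructureMask",
    "ProtocolSpec",
    "GridMismatchError",
    "NonOverlappingGridsError",
    "grids_compatible",
    "resample_to",
    "resample_mask_to",
    "load_dose_nifti",
    "save_dose_nifti",
    "load_mask_nifti",
    "save_mask_nifti",
]

SPACING_ATOL_MM = 1e-6
ORIGIN_ATOL_MM = 1e-3


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


class NonOverlappingGridsError(ValueError):
    """Resampling would extrapolate beyond the allowed margin."""


@dataclass(frozen=True)
class GridHeader:
    """Geometry of a voxel grid, independent of its payload."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3-D with every axis >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm, rows = points."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        mm = np.asarray(mm, dtype=float)
        return (mm - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class DoseGrid:
    """A 3-D planned-dose scalar field in cGy on a :class:`GridHeader`."""

    values: np.ndarray
    header: GridHeader

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("dose values must be 3-D (z, y, x)")
        if tuple(self.values.shape) != self.header.shape:
            raise ValueError(
                f"dose shape {self.values.shape} does not match header {self.header.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def spacing(self) -> Tuple[float, float, float]:
        return self.header.spacing

    @property
    def origin(self) -> Tuple[float, float, float]:
        return self.header.origin


@dataclass
class StructureMask:
    """Binary organ occupancy on a :class:`GridHeader`.

    ``present`` is False when a segmentation model produced no structure
    (or when erosion removed every voxel); an absent mask is always empty.
    ``status`` distinguishes *why* a mask is absent.
    """

    values: np.ndarray
    header: GridHeader
    present: bool = True
    status: str = "ok"  # ok | failed | eroded-away

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask values must be 3-D (z, y, x)")
        if tuple(self.values.shape) != self.header.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match header {self.header.shape}"
            )
        if not self.present:
            if self.values.any():
                raise ValueError("an absent mask must be empty")
        else:
            if not self.values.any():
                raise ValueError("a present mask must occupy at least one voxel")
            if self.status not in ("ok",):
                raise ValueError(f"present mask cannot carry status {self.status!r}")

    @classmethod
    def absent(cls, header: GridHeader, status: str = "failed") -> "StructureMask":
        return cls(np.zeros(header.shape, dtype=bool), header, present=False, status=status)

    def voxel_count(self) -> int:
        return int(self.values.sum())

    def volume_mm3(self) -> float:
        return self.voxel_count() * self.header.voxel_volume_mm3()


@dataclass(frozen=True)
class ProtocolSpec:
    """Prescription protocol: label, total dose (cGy) and fraction count."""

    name: str
    prescription_cGy: float
    fractions: int

    def __post_init__(self) -> None:
        if self.prescription_cGy <= 0:
            raise ValueError("prescription must be positive")
        if self.fractions <= 0:
            raise ValueError("fraction count must be positive")


Volume = Union[DoseGrid, StructureMask]


def grids_compatible(a: Volume, b: Volume) -> bool:
    """True iff two volumes share shape, spacing and origin.

    Spacing is compared to 1e-6 mm and origin to 1e-3 mm, absorbing header
    round-trips through file formats.  Payload values never matter.
    """
    ha, hb = a.header, b.header
    if ha.shape != hb.shape:
        return False
    if not np.allclose(ha.spacing, hb.spacing, rtol=0.0, atol=SPACING_ATOL_MM):
        return False
    return bool(np.allclose(ha.origin, hb.origin, rtol=0.0, atol=ORIGIN_ATOL_MM))


def require_compatible(a: Volume, b: Volume, what: str = "volumes") -> None:
    if not grids_compatible(a, b):
        raise GridMismatchError(
            f"{what} are on incompatible grids: "
            f"{a.header.shape}/{a.header.spacing}/{a.header.origin} vs "
            f"{b.header.shape}/{b.header.spacing}/{b.header.origin}"
        )


def _target_index_coords(src: GridHeader, target: GridHeader) -> np.ndarray:
    """Fractional source-index coordinates of every target voxel centre.

    Returns an array of shape (3,) + target.shape suitable for
    ``ndimage.map_coordinates``.
    """
    axes = [
        (target.voxel_centers_mm(k) - src.origin[k]) / src.spacing[k] for k in range(3)
    ]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack(grids, axis=0)


def _check_overlap(src: GridHeader, coords: np.ndarray, margin_voxels: float) -> None:
    for k in range(3):
        lo = coords[k].min()
        hi = coords[k].max()
        if lo < -margin_voxels or hi > src.shape[k] - 1 + margin_voxels:
            raise NonOverlappingGridsError(
                f"target grid extends beyond source axis {k} by more than "
                f"{margin_voxels} voxel(s): index range [{lo:.3f}, {hi:.3f}] "
                f"vs source [0, {src.shape[k] - 1}]"
            )


def resample_to(
    src: DoseGrid,
    target_header: GridHeader,
    interpolation: str = "trilinear",
    margin_voxels: float = 0.5,
) -> DoseGrid:
    """Resample a dose grid onto a new header with the same axis orientation.

    ``interpolation`` is ``"trilinear"`` or ``"nearest"``.  Target voxels
    more than ``margin_voxels`` outside the source extent raise
    :class:`NonOverlappingGridsError`; within the margin, edge values are
    extended.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if target_header == src.header:
        return DoseGrid(src.values.copy(), src.header)
    coords = _target_index_coords(src.header, target_header)
    _check_overlap(src.header, coords, margin_voxels)
    order = 1 if interpolation == "trilinear" else 0
    out = ndimage.map_coordinates(src.values, coords, order=order, mode="nearest")
    return DoseGrid(out.reshape(target_header.shape), target_header)


def resample_mask_to(
    src: StructureMask, target_header: GridHeader, margin_voxels: float = 0.5
) -> StructureMask:
    """Nearest-neighbour mask resampling; output stays binary."""
    if not src.present:
        return StructureMask.absent(target_header, status=src.status)
    if target_header == src.header:
        return StructureMask(src.values.copy(), src.header, present=True)
    coords = _target_index_coords(src.header, target_header)
    _check_overlap(src.header, coords, margin_voxels)
    out = ndimage.map_coordinates(
        src.values.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    if not out.any():
        return StructureMask.absent(target_header, status="eroded-away")
    return StructureMask(out.reshape(target_header.shape), target_header, present=True)


# ---------------------------------------------------------------------------
# NIfTI I/O.  Internal order is (z, y, x); NIfTI arrays are stored (x, y, z)
# with a diagonal affine carrying spacing and origin.
# ---------------------------------------------------------------------------

def _affine(header: GridHeader) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = header.spacing[::-1]
    aff[:3, 3] = header.origin[::-1]
    return aff


def _header_from_nifti(img: nib.Nifti1Image) -> GridHeader:
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-6):
        raise ValueError("only axis-aligned (diagonal-affine) NIfTI volumes are supported")
    spacing_xyz = np.diag(aff[:3, :3]).astype(float)
    if np.any(spacing_xyz <= 0):
        raise ValueError("negative or zero spacing in NIfTI affine is not supported")
    origin_xyz = aff[:3, 3].astype(float)
    shape_xyz = img.shape
    if len(shape_xyz) != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {shape_xyz}")
    return GridHeader(
        shape=tuple(int(s) for s in shape_xyz[::-1]),
        spacing=tuple(float(s) for s in spacing_xyz[::-1]),
        origin=tuple(float(o) for o in origin_xyz[::-1]),
    )


def save_dose_nifti(dose: DoseGrid, path: Union[str, Path]) -> None:
    data = np.asarray(dose.values, dtype=np.float32).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, _affine(dose.header)), str(path))


def load_dose_nifti(path: Union[str, Path]) -> DoseGrid:
    img = nib.load(str(path))
    header = _header_from_nifti(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64).transpose(2, 1, 0)
    return DoseGrid(data, header)


def save_mask_nifti(mask: StructureMask, path: Union[str, Path]) -> None:
    data = mask.values.astype(np.uint8).transpose(2, 1, 0)
    nib.save(nib.Nifti1Image(data, _affine(mask.header)), str(path))


def load_mask_nifti(path: Union[str, Path], present: bool = True) -> StructureMask:
    img = nib.load(str(path))
    header = _header_from_nifti(img)
    data = np.asarray(img.get_fdata()).transpose(2, 1, 0) > 0.5
    if not present or not data.any():
        return StructureMask.absent(header, status="failed")
    return StructureMask(data, header, present=True)
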