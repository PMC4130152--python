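"""NIfTI volume I/O and voxel geometry.

All processing downstream happens in voxel space on plain numpy arrays;
the only geometric information ever consulted is the voxel spacing
(dx, dy, dz) in millimetres, which converts voxel counts to volumes and
voxel offsets to physical distances.  Orientation is carried through the
NIfTI affine untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "BinaryMask",
    "LabelMap",
    "read_volume",
    "write_volume",
    "write_mask",
    "write_labelmap",
    "voxel_volume_ml",
]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in mm.

    ``data`` is float, free of NaN/Inf; ``spacing`` components are
    strictly positive.  Voxel indices are 0-based.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data contains NaN or Inf")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume on the same grid carrying ``data``."""
        return Volume(data, self.spacing, self.affine.copy())


@dataclass
class BinaryMask:
    """A voxel-aligned boolean mask sharing the grid of the Volume it annotates."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())

    def volume_ml(self) -> float:
        return self.count() * voxel_volume_ml(self.spacing)


@dataclass
class LabelMap:
    """Non-negative integer label image; 0 is background, labels run 1..K."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {data.shape}")
        if data.size and data.min() < 0:
            raise ValueError("label map contains negative labels")
        self.data = data.astype(np.int32)
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_labels(self) -> int:
        return int(self.data.max())

    def labels(self) -> list[int]:
        out = np.unique(self.data)
        return [int(v) for v in out if v != 0]


def same_grid(a, b) -> None:
    """Raise if two carriers do not share shape and spacing."""
    if a.shape != b.shape:
        raise ValueError(f"grid shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"spacing mismatch: {a.spacing} vs {b.spacing}")


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 image as a float Volume.

    Raises on non-3D images, non-positive header spacing, or non-finite
    voxels (corrupt data is rejected rather than silently propagated).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing {spacing}")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains NaN/Inf voxels")
    return Volume(data, spacing, np.asarray(img.affine, dtype=float))


def write_volume(vol: Volume, path: str | Path, dtype=np.float32) -> None:
    """Write a Volume to NIfTI-1; float32 on disk round-trips losslessly
    for float32-representable data."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a BinaryMask as uint8 0/1 NIfTI."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    aff = affine if affine is not None else _default_affine(mask.spacing)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def write_labelmap(lm: LabelMap, path: str | Path, affine: np.ndarray | None = None) -> None:
    """Write a LabelMap as uint32 NIfTI."""
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"output directory does not exist: {path.parent}")
    aff = affine if affine is not None else _default_affine(lm.spacing)
    img = nib.Nifti1Image(lm.data.astype(np.uint32), aff)
    img.header.set_zooms(lm.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a NIfTI mask; any nonzero voxel is True."""
    vol = read_volume(path)
    return BinaryMask(vol.data != 0, vol.spacing)


def voxel_volume_ml(spacing) -> float:
    """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
    dx, dy, dz = _check_spacing(spacing)
    return dx * dy * dz / 1000.0
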