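"""3D volume containers and file I/O.

All grids are indexed (z, y, x) with 0-based voxel coordinates; physical
positions are voxel index × ``voxel_size`` (μm). Only isotropic grids are
supported, matching ex vivo micro-CT acquisitions of cast specimens.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = ["VolumeImage", "BinaryMask", "SkeletonVolume", "AnisotropicGridError"]


class AnisotropicGridError(ValueError):
    """Raised for anisotropic voxel grids; resample to isotropic first."""


def _check_3d(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {values.shape}")
    return values


@dataclass
class _Grid3D:
    values: np.ndarray
    voxel_size: float = 4.5  # μm, isotropic
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.values = _check_3d(self.values)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive (μm)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def _like(self, values: np.ndarray):
        return dataclasses.replace(self, values=values, provenance=dict(self.provenance))

    # --- file I/O -----------------------------------------------------
    def to_tiff(self, path: str | Path) -> None:
        """Write as a multi-page TIFF stack with voxel size in the metadata."""
        data = self._export_array()
        tifffile.imwrite(
            str(path), data, metadata={"voxel_size_um": float(self.voxel_size)}
        )

    def to_nifti(self, path: str | Path) -> None:
        """Write as NIfTI; voxel size stored in mm (μm × 10⁻³) per convention."""
        mm = self.voxel_size * 1e-3
        affine = np.diag([mm, mm, mm, 1.0])
        img = nib.Nifti1Image(self._export_array().transpose(2, 1, 0), affine)
        nib.save(img, str(path))

    def _export_array(self) -> np.ndarray:
        v = self.values
        if v.dtype == bool:
            return (v.astype(np.uint8)) * np.uint8(255)
        return np.asarray(v, dtype=np.float32)

    @classmethod
    def from_tiff(cls, path: str | Path, voxel_size: float | None = None):
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            if voxel_size is None:
                meta = tif.shaped_metadata or ({},)
                voxel_size = float(meta[0].get("voxel_size_um", 4.5))
        return cls(cls._import_array(data), voxel_size)

    @classmethod
    def from_nifti(cls, path: str | Path):
        img = nib.load(str(path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        if not np.allclose(zooms, zooms[0], rtol=1e-4):
            raise AnisotropicGridError(
                f"anisotropic voxels {zooms} mm; resample to an isotropic grid first"
            )
        data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
        return cls(cls._import_array(data), float(zooms[0]) * 1e3)

    @staticmethod
    def _import_array(data: np.ndarray) -> np.ndarray:
        return np.asarray(data, dtype=np.float32)


@dataclass
class VolumeImage(_Grid3D):
    """3D grayscale volume (float32) on an isotropic grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values, dtype=np.float32)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")


@dataclass
class _BoolGrid(_Grid3D):
    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = np.asarray(self.values).astype(bool)

    @staticmethod
    def _import_array(data: np.ndarray) -> np.ndarray:
        return np.asarray(data) > 0

    def count(self) -> int:
        return int(self.values.sum())


@dataclass
class BinaryMask(_BoolGrid):
    """Binary vessel segmentation aligned with its source volume."""

    def volume_um3(self) -> float:
        """Segmented vascular volume: true-voxel count × voxel_size³ (μm³)."""
        return self.count() * float(self.voxel_size) ** 3


@dataclass
class SkeletonVolume(_BoolGrid):
    """Unit-width centerline voxel set of a vessel mask."""


def write_provenance(path: str | Path, record: dict) -> None:
    """Drop a provenance JSON next to an output file."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
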