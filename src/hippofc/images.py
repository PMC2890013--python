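"""Lightweight containers for 4D BOLD series and 3D ROI masks.

Everything downstream operates on plain numpy arrays carried together with
the grid-to-world affine and the repetition time (TR). NIfTI-1 round-trips
go through nibabel; TR is stored in the header's fourth pixdim as nibabel's
``set_zooms`` does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries", "ROIMask", "load_series", "load_mask"]


@dataclass
class VolumeSeries:
    """A 4D scalar field (x, y, z, t) with affine and repetition time.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Voxel intensities, arbitrary BOLD units.
    affine : ndarray, shape (4, 4)
        Grid-index to world-millimetre affine.
    tr_s : float
        Repetition time in seconds (sampling interval of the time axis).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries data must be 4D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine)
        zooms = tuple(self.voxel_size_mm) + (self.tr_s,)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, tr_s: float | None = None) -> "VolumeSeries":
        if tr_s is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or not zooms[3] > 0:
                raise ValueError("TR not recorded in header; pass tr_s explicitly")
            tr_s = float(zooms[3])
        return cls(np.asarray(img.dataobj), np.asarray(img.affine), tr_s)


@dataclass
class ROIMask:
    """A 3D binary mask on the same grid as the functional series."""

    data: np.ndarray
    affine: np.ndarray
    name: str = field(default="roi")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"ROIMask data must be 3D, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image, name: str = "roi") -> "ROIMask":
        return cls(np.asarray(img.dataobj) > 0, np.asarray(img.affine), name)


def load_series(path, tr_s: float | None = None) -> VolumeSeries:
    """Read a 4D NIfTI-1 file; TR from the header unless overridden."""
    return VolumeSeries.from_nifti(nib.load(str(path)), tr_s=tr_s)


def load_mask(path, name: str = "roi") -> ROIMask:
    return ROIMask.from_nifti(nib.load(str(path)), name=name)


def check_same_grid(a, b, what: str = "inputs") -> None:
    """Raise if two objects live on different grids."""
    if a.data.shape[:3] != b.data.shape[:3]:
        raise ValueError(
            f"grid mismatch between {what}: {a.data.shape[:3]} vs {b.data.shape[:3]}"
        )
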