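"""Core image containers shared by every pipeline stage.

Volumes live on axis-aligned grids: a 3-D array plus per-axis voxel spacing
(mm) and a world-space origin (mm, the center of voxel ``(0, 0, 0)``). All
cross-grid arithmetic (resampling, mask transfer) happens in world
coordinates so PET and MRI grids with different resolutions compose
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "ImageVolume", "RoiMask", "load_volume", "save_volume"]


@dataclass(frozen=True)
class Grid:
    """An axis-aligned sampling grid: shape (voxels), spacing and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world coordinates of the outermost voxel centers."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            np.asarray(self.origin[i]) + np.arange(self.shape[i]) * self.spacing[i]
            for i in range(3)
        )

    def index_grid_world(self) -> np.ndarray:
        """Dense (3, *shape) array of world coordinates for every voxel center."""
        ax = self.voxel_centers()
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=0)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ImageVolume:
    """A scalar field on a :class:`Grid` with a modality tag (e.g. 'SUV', 'ADC')."""

    data: np.ndarray
    grid: Grid
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    def same_grid(self, other: "ImageVolume | RoiMask") -> bool:
        return self.grid == other.grid


@dataclass
class RoiMask:
    """A binary region of interest on a named grid.

    ``tissue_class`` distinguishes lesions from the normal-tissue regions used
    as tumor-to-background references ('lesion', 'contralateral',
    'normal-organ').
    """

    data: np.ndarray
    grid: Grid
    name: str
    tissue_class: str = "lesion"
    laterality: str = ""

    _ALLOWED = ("lesion", "contralateral", "normal-organ")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"mask shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if self.tissue_class not in self._ALLOWED:
            raise ValueError(
                f"tissue_class must be one of {self._ALLOWED}, got {self.tissue_class!r}"
            )
        if not self.data.any():
            raise ValueError(f"ROI mask {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_ml


def save_volume(vol: ImageVolume | RoiMask, path: str) -> None:
    """Write a volume or mask as NIfTI; masks are stored as uint8."""
    data = vol.data.astype(np.uint8) if isinstance(vol, RoiMask) else np.asarray(vol.data)
    img = nib.Nifti1Image(data, vol.grid.affine())
    nib.save(img, path)


def load_volume(path: str, modality: str = "") -> ImageVolume:
    """Read a NIfTI volume onto an axis-aligned :class:`Grid`.

    Only diagonal affines (no rotation/shear) are supported; the pipeline
    assumes co-registered, axis-aligned acquisitions.
    """
    img = nib.load(path)
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError(f"{path}: only axis-aligned (diagonal) affines are supported")
    spacing = tuple(float(d) for d in np.diag(aff[:3, :3]))
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: negative or zero spacing in affine; reorient first")
    data = np.asarray(img.get_fdata())
    grid = Grid(tuple(int(s) for s in data.shape), spacing, tuple(float(o) for o in aff[:3, 3]))
    return ImageVolume(data, grid, modality=modality)
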