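"""3D count-volume data model and grid utilities.

Volumes are reconstructed SPECT count images: a dense array of nonnegative
intensities on a regular grid with isotropic-or-not voxel spacing in mm.
Intensities are stored as floating point even though raw counts are integral,
so that interpolation and reconstruction-like smoothing do not truncate.

Coordinate convention: voxel indices are 0-based and the world coordinate of
the *center* of voxel ``i`` along an axis is ``origin + (i + 0.5) * spacing``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Grid:
    """A regular 3D sampling grid: voxel counts, spacing (mm), origin (mm)."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("grid needs 3 dims, 3 spacings and 3 origin components")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be positive, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (3, nx, ny, nz)."""
        idx = np.indices(self.dims, dtype=float)
        sp = np.asarray(self.spacing).reshape(3, 1, 1, 1)
        og = np.asarray(self.origin).reshape(3, 1, 1, 1)
        return og + (idx + 0.5) * sp

    def center(self) -> np.ndarray:
        """World coordinate of the grid's geometric center."""
        return np.asarray(self.origin) + 0.5 * np.asarray(self.dims) * np.asarray(
            self.spacing
        )


@dataclass
class Volume3D:
    """A 3D count image: nonnegative finite intensities on a :class:`Grid`.

    ``values`` is indexed ``[i, j, k]`` matching ``grid.dims``.
    """

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("volume contains negative intensities")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.grid.dims

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.grid)


@dataclass
class MaskVolume:
    """A binary volume of interest on the same grid as an associated Volume3D."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.values = vals.astype(np.uint8)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid dims {self.grid.dims}"
            )

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the mask."""
        return int(self.values.sum())

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)


def dice(a: MaskVolume, b: MaskVolume) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two masks on the same grid."""
    if a.values.shape != b.values.shape:
        raise ValueError("masks must share a grid")
    inter = int(np.logical_and(a.as_bool(), b.as_bool()).sum())
    denom = a.n_voxels + b.n_voxels
    if denom == 0:
        return 1.0
    return 2.0 * inter / denom


def _affine_from_grid(grid: Grid) -> np.ndarray:
    # NIfTI places voxel center i at A @ (i, 1); our convention puts it at
    # origin + (i + 0.5) * spacing, so the translation carries the half-voxel.
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = np.asarray(grid.origin) + 0.5 * np.asarray(grid.spacing)
    return aff


def _grid_from_nifti(img: nib.Nifti1Image) -> Grid:
    aff = img.affine
    lin = aff[:3, :3]
    spacing = np.sqrt((lin**2).sum(axis=0))
    off_diag = lin - np.diag(np.diag(lin))
    if np.any(np.abs(off_diag) > 1e-3 * spacing.min()) or np.any(np.diag(lin) <= 0):
        raise ValueError(
            "only axis-aligned volumes with positive voxel directions are supported"
        )
    origin = aff[:3, 3] - 0.5 * spacing
    return Grid(tuple(img.shape[:3]), tuple(spacing), tuple(origin))


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a 3D single-frame NIfTI image as a :class:`Volume3D`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    non-3D content or negative intensities.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"not a 3D volume: {path} has {img.ndim} dimensions")
    grid = _grid_from_nifti(img)
    data = np.asarray(img.get_fdata(), dtype=float)
    if np.any(data < 0):
        raise ValueError(f"volume {path} contains negative intensities")
    return Volume3D(data, grid)


def write_volume(volume: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1 (.nii / .nii.gz); roundtrips with read_volume."""
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine_from_grid(volume.grid))
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike) -> MaskVolume:
    """Read a binary {0,1} NIfTI mask."""
    vol = read_volume(path)
    return MaskVolume(np.rint(vol.values).astype(np.uint8), vol.grid)


def write_mask(mask: MaskVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from_grid(mask.grid))
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def resample_to_grid(
    volume: Volume3D | MaskVolume,
    target: Grid,
    method: str = "trilinear",
) -> Volume3D | MaskVolume:
    """Resample a volume (or mask) onto ``target``, sampling at voxel centers.

    ``method`` is ``"nearest"`` (preserves the input value set) or
    ``"trilinear"`` (output bounded by the input min/max). Voxels falling
    outside the source field of view are filled with 0 (cold background).
    Masks resampled with trilinear interpolation are re-binarized at 0.5.
    """
    if method not in ("nearest", "trilinear"):
        raise ValueError(f"unknown resampling method: {method!r}")
    order = 0 if method == "nearest" else 1
    src = volume.grid
    world = target.voxel_centers()  # (3, nx, ny, nz)
    sp = np.asarray(src.spacing).reshape(3, 1, 1, 1)
    og = np.asarray(src.origin).reshape(3, 1, 1, 1)
    coords = (world - og) / sp - 0.5  # fractional source indices
    vals = volume.values.astype(float)
    out = ndimage.map_coordinates(vals, coords, order=order, mode="constant", cval=0.0)
    if isinstance(volume, MaskVolume):
        return MaskVolume((out >= 0.5).astype(np.uint8), target)
    return Volume3D(out, target)
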