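"""Volume / table I/O and grid bookkeeping for voxel-based morphometry stacks.

A :class:`VolumeStack` is the universal in-memory carrier of modulated
gray-matter-volume (GMV) maps: a ``subjects x masked-voxels`` matrix bound to a
3D grid and a boolean analysis mask.  All downstream statistics (similarity,
reliability, mass-univariate GLMs, MVPA) operate on this representation.

Voxel ordering is the fixed C-order flattening of the mask indices; masked
vectorization and un-vectorization are exact inverses on mask voxels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Grid",
    "VolumeStack",
    "GridMismatchError",
    "MetadataError",
    "EmptyMaskError",
    "GAUSSIAN_FWHM_FACTOR",
    "sigma_fwhm_convert",
    "smooth_stack",
    "smooth_volume",
    "validate_table",
    "load_table",
    "load_stack",
    "write_stack",
    "intersect_masks",
]

#: exact FWHM / sigma ratio for a Gaussian, 2 * sqrt(2 * ln 2)
GAUSSIAN_FWHM_FACTOR: float = 2.0 * math.sqrt(2.0 * math.log(2.0))


class GridMismatchError(ValueError):
    """Volumes do not share shape/spacing with the analysis mask."""


class MetadataError(ValueError):
    """Participants table does not cover or match the image stack."""


class EmptyMaskError(ValueError):
    """Analysis mask contains no voxels."""


@dataclass(frozen=True)
class Grid:
    """Regular 3D sampling grid (shape in voxels, spacing in mm)."""

    shape: tuple[int, ...]
    spacing: tuple[float, ...] = (2.0, 2.0, 2.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if len(self.shape) != len(self.spacing):
            raise ValueError("shape and spacing dimensionality differ")
        if any(s < 1 for s in self.shape):
            raise ValueError("all grid dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        """Scaled-identity voxel-to-mm affine (RAS+, origin at voxel 0)."""
        aff = np.eye(4)
        for i, sp in enumerate(self.spacing[:3]):
            aff[i, i] = sp
        return aff


@dataclass
class VolumeStack:
    """Stack of co-registered masked volumes, one row per subject.

    ``data[i, j]`` is the GMV of subject ``subject_ids[i]`` at the j-th mask
    voxel (C-order flattening of ``mask``).
    """

    data: np.ndarray
    grid: Grid
    mask: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise GridMismatchError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape}"
            )
        n_mask = int(self.mask.sum())
        if n_mask == 0:
            raise EmptyMaskError("analysis mask contains no voxels")
        if self.data.ndim != 2 or self.data.shape[1] != n_mask:
            raise GridMismatchError(
                f"data has {self.data.shape[-1] if self.data.ndim else 0} columns, "
                f"mask has {n_mask} voxels"
            )
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:04d}" for i in range(self.data.shape[0])]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != self.data.shape[0]:
            raise MetadataError("subject_ids length != number of rows")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise MetadataError("subject_ids are not unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def unmask(self, row: int | np.ndarray) -> np.ndarray:
        """Re-embed one subject (index or vector) into the full 3D grid."""
        vec = self.data[row] if np.isscalar(row) else np.asarray(row, dtype=np.float64)
        vol = np.zeros(self.grid.shape, dtype=np.float64)
        vol[self.mask] = vec
        return vol

    def to_4d(self) -> np.ndarray:
        """Full 4D array (x, y, z, subject), zeros outside the mask."""
        out = np.zeros(self.grid.shape + (self.n_subjects,), dtype=np.float64)
        out[self.mask, :] = self.data.T
        return out

    @classmethod
    def from_volumes(
        cls,
        volumes: np.ndarray,
        grid: Grid,
        mask: np.ndarray,
        subject_ids: Sequence[str] | None = None,
    ) -> "VolumeStack":
        """Build a stack from an (n_subjects, *grid.shape) array."""
        volumes = np.asarray(volumes, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        data = volumes[:, mask] if volumes.ndim == len(grid.shape) + 1 else volumes[mask]
        return cls(data=data, grid=grid, mask=mask, subject_ids=list(subject_ids or []))

    def with_data(self, data: np.ndarray) -> "VolumeStack":
        return VolumeStack(data=data, grid=self.grid, mask=self.mask,
                           subject_ids=list(self.subject_ids))

    def select_subjects(self, ids: Sequence[str]) -> "VolumeStack":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise MetadataError(f"subjects not in stack: {missing[:5]}")
        rows = [index[s] for s in ids]
        return VolumeStack(data=self.data[rows], grid=self.grid, mask=self.mask,
                           subject_ids=list(ids))


# ---------------------------------------------------------------------------
# participants table


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a participants table (subject_id, sex in {F,M}, age>0, tiv>0)."""
    required = {"subject_id", "sex", "age", "tiv"}
    missing = required - set(table.columns)
    if missing:
        raise MetadataError(f"participants table missing columns: {sorted(missing)}")
    table = table.copy()
    table["subject_id"] = table["subject_id"].astype(str)
    if table["subject_id"].duplicated().any():
        raise MetadataError("duplicate subject_id in participants table")
    if not set(table["sex"]) <= {"F", "M"}:
        raise MetadataError("sex must be coded F/M")
    if (table["age"] <= 0).any():
        raise MetadataError("ages must be positive")
    if (table["tiv"] <= 0).any():
        raise MetadataError("TIV must be positive")
    return table.reset_index(drop=True)


def load_table(path: str | Path) -> pd.DataFrame:
    return validate_table(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_img(img: nib.Nifti1Image) -> Grid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Grid(shape=tuple(int(s) for s in img.shape[:3]), spacing=zooms)


def load_stack(
    image_path: str | Path | Sequence[str | Path],
    mask_path: str | Path,
    table_path: str | Path | None = None,
) -> tuple[VolumeStack, pd.DataFrame | None]:
    """Load a 4D NIfTI (or list of 3D NIfTIs) plus mask and optional TSV table.

    Rows follow the table's subject order when a table is given.  All volumes
    must share shape and spacing with the mask.
    """
    mask_img = nib.load(str(mask_path))
    grid = _grid_from_img(mask_img)
    mask = np.asarray(mask_img.dataobj) > 0.5
    if not mask.any():
        raise EmptyMaskError(f"mask {mask_path} has no voxels")

    if isinstance(image_path, (str, Path)):
        img = nib.load(str(image_path))
        if tuple(img.shape[:3]) != grid.shape or not np.allclose(
            img.header.get_zooms()[:3], grid.spacing, atol=1e-4
        ):
            raise GridMismatchError(f"{image_path} does not match mask grid")
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[..., None]
        volumes = np.moveaxis(arr, -1, 0)
    else:
        vols = []
        for p in image_path:
            img = nib.load(str(p))
            if tuple(img.shape[:3]) != grid.shape or not np.allclose(
                img.header.get_zooms()[:3], grid.spacing, atol=1e-4
            ):
                raise GridMismatchError(f"{p} does not match mask grid")
            vols.append(np.asarray(img.dataobj, dtype=np.float64))
        volumes = np.stack(vols, axis=0)

    stack = VolumeStack.from_volumes(volumes, grid, mask)
    table = None
    if table_path is not None:
        table = load_table(table_path)
        if len(table) != stack.n_subjects:
            raise MetadataError(
                f"table has {len(table)} rows, stack has {stack.n_subjects} subjects"
            )
        stack.subject_ids = list(table["subject_id"])
    return stack, table


def write_stack(
    stack: VolumeStack,
    image_path: str | Path,
    mask_path: str | Path | None = None,
    table: pd.DataFrame | None = None,
    table_path: str | Path | None = None,
) -> None:
    """Write a stack as 4D NIfTI (+ optional mask NIfTI and participants TSV)."""
    aff = stack.grid.affine()
    nib.Nifti1Image(stack.to_4d(), aff).to_filename(str(image_path))
    if mask_path is not None:
        nib.Nifti1Image(stack.mask.astype(np.uint8), aff).to_filename(str(mask_path))
    if table is not None and table_path is not None:
        table.to_csv(table_path, sep="\t", index=False)


def intersect_masks(stacks: Iterable[VolumeStack]) -> list[VolumeStack]:
    """Restrict a collection of stacks to their common mask.

    Required before any voxel-wise between-pipeline comparison; the output
    stacks share one mask and identical voxel ordering.
    """
    stacks = list(stacks)
    if not stacks:
        return []
    grid = stacks[0].grid
    common = np.ones(grid.shape, dtype=bool)
    for s in stacks:
        if tuple(s.grid.shape) != tuple(grid.shape):
            raise GridMismatchError("stacks are on different grids")
        common &= s.mask
    if not common.any():
        raise EmptyMaskError("intersection of masks is empty")
    out = []
    for s in stacks:
        sel = common[s.mask]  # columns of s.data inside the common mask
        out.append(VolumeStack(data=s.data[:, sel], grid=grid, mask=common,
                               subject_ids=list(s.subject_ids)))
    return out


# ---------------------------------------------------------------------------
# smoothing & kernel-width conversion


def sigma_fwhm_convert(
    value: float,
    direction: str = "sigma_to_fwhm",
    factor: float = GAUSSIAN_FWHM_FACTOR,
) -> float:
    """Convert between Gaussian sigma and FWHM (both in mm).

    The exact conversion constant is ``2 * sqrt(2 * ln 2) = 2.3548...``;
    VBM tooling frequently uses the rounded factor 2.3 (e.g. fslmaths sigma
    3.5 is quoted as FWHM 3.5 x 2.3 = 8.05 ~ 8 mm).

    Parameters
    ----------
    value : kernel width in mm.
    direction : "sigma_to_fwhm" or "fwhm_to_sigma".
    factor : conversion constant; default the exact one.
    """
    if value < 0:
        raise ValueError("kernel width must be non-negative")
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if direction == "sigma_to_fwhm":
        return value * factor
    if direction == "fwhm_to_sigma":
        return value / factor
    raise ValueError(f"unknown direction {direction!r}")


def smooth_volume(vol: np.ndarray, fwhm: float, spacing: Sequence[float]) -> np.ndarray:
    """Gaussian-smooth one 3D volume (zero padding outside the volume)."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return np.asarray(vol, dtype=np.float64).copy()
    sigma_vox = [fwhm / GAUSSIAN_FWHM_FACTOR / sp for sp in spacing]
    return ndimage.gaussian_filter(np.asarray(vol, dtype=np.float64), sigma_vox,
                                   mode="constant", cval=0.0)


def smooth_stack(stack: VolumeStack, fwhm: float) -> VolumeStack:
    """Per-subject 3D Gaussian smoothing on the unmasked volume, re-masked.

    fwhm 0 is the identity.  Values outside the mask are treated as zero
    before convolution (zero padding), the common VBM convention; masked-edge
    voxels are therefore pulled toward zero.
    """
    if fwhm == 0:
        return stack.with_data(stack.data.copy())
    out = np.empty_like(stack.data)
    for i in range(stack.n_subjects):
        out[i] = smooth_volume(stack.unmask(i), fwhm, stack.grid.spacing)[stack.mask]
    return stack.with_data(out)
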