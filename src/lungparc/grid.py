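"""Voxel-lattice geometry and volume containers.

All volumes in the toolkit share one geometry model: an axis-aligned lattice
described by :class:`ImageGrid` (dims in voxels, spacing in mm/voxel, origin =
world position of the center of voxel ``(0, 0, 0)``).  Indexing is 0-based and
the world <-> index mapping is diagonal; oblique orientations are rejected at
the NIfTI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "LabelVolume",
    "read_nifti_scalar",
    "read_nifti_labels",
    "write_nifti",
]


@dataclass(frozen=True)
class ImageGrid:
    """Geometry of a 3-D voxel lattice.

    Parameters
    ----------
    dims : tuple of 3 int
        Number of voxels per axis, each >= 1.
    spacing : tuple of 3 float
        Voxel edge length per axis in mm, each > 0.
    origin : tuple of 3 float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- coordinate transforms -------------------------------------------------

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world coordinates (mm)."""
        i = np.asarray(indices, dtype=float)
        return i * np.asarray(self.spacing) + np.asarray(self.origin)

    def round_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel index for world points (round half to even, numpy)."""
        return np.rint(self.world_to_index(points_mm)).astype(np.int64)

    def contains_index(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx))
        dims = np.asarray(self.dims)
        return np.all((idx >= 0) & (idx < dims), axis=-1)

    @property
    def affine(self) -> np.ndarray:
        """Diagonal NIfTI affine built from spacing and origin."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def voxel_centers_mm(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask."""
        if mask is not None:
            idx = np.argwhere(mask)
        else:
            idx = np.indices(self.dims).reshape(3, -1).T
        return self.index_to_world(idx)


@dataclass
class ScalarVolume:
    """A float-valued volume on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )


@dataclass
class LabelVolume:
    """An integer-labeled volume; 0 means background."""

    grid: ImageGrid
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {self.labels.dtype}")
        if self.labels.shape != self.grid.dims:
            raise ValueError(
                f"labels shape {self.labels.shape} != grid dims {self.grid.dims}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def label_set(self) -> set[int]:
        return set(int(v) for v in np.unique(self.labels) if v != 0)


def check_same_grid(a, b) -> None:
    """Raise ValueError when two volumes do not share a grid."""
    ga, gb = a.grid, b.grid
    if ga.dims != gb.dims or not np.allclose(ga.spacing, gb.spacing) or not np.allclose(
        ga.origin, gb.origin
    ):
        raise ValueError(f"grid mismatch: {ga} vs {gb}")


# -- NIfTI I/O ----------------------------------------------------------------


def _grid_and_data(img: nib.Nifti1Image) -> tuple[ImageGrid, np.ndarray]:
    """Extract a diagonal-affine grid, flipping negative axes to positive spacing."""
    aff = np.asarray(img.affine, dtype=float)
    lin = aff[:3, :3]
    off_diag = lin - np.diag(np.diag(lin))
    if np.max(np.abs(off_diag)) > 1e-6 * max(1.0, np.max(np.abs(lin))):
        raise ValueError(
            "NIfTI affine is not axis-aligned (diagonal up to flips); "
            "oblique orientations are not supported"
        )
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    spacing = np.diag(lin).copy()
    origin = aff[:3, 3].copy()
    for ax in range(3):
        if spacing[ax] == 0:
            raise ValueError("NIfTI affine has zero spacing on an axis")
        if spacing[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] + (data.shape[ax] - 1) * spacing[ax]
            spacing[ax] = -spacing[ax]
    grid = ImageGrid(tuple(data.shape), tuple(spacing), tuple(origin))
    return grid, np.ascontiguousarray(data)


def read_nifti_scalar(path) -> ScalarVolume:
    grid, data = _grid_and_data(nib.load(str(path)))
    return ScalarVolume(grid, data.astype(np.float64))


def read_nifti_labels(path) -> LabelVolume:
    grid, data = _grid_and_data(nib.load(str(path)))
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{path}: label volume contains non-integer values")
        data = rounded
    return LabelVolume(grid, data.astype(np.int32))


def write_nifti(volume: ScalarVolume | LabelVolume, path) -> None:
    """Write a volume as NIfTI-1; float32 for scalars, uint16 for labels."""
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.uint16)
    else:
        data = volume.values.astype(np.float32)
    img = nib.Nifti1Image(data, volume.grid.affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))
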