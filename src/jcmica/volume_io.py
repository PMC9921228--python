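"""Brain volumes, masks, atlases, and connectivity matrices.

This module fixes the voxel-vectorization convention used by every other
part of the package: masked voxels are ordered by ascending linear index
with the **first** grid axis varying fastest (Fortran order, 0-based).
Every matrix whose rows or columns "are voxels" uses this ordering.

Volumes are NIfTI-1 (via nibabel); sparse connectivity matrices are
MatrixMarket (MTX); dense ones live in HDF5; atlas label names come from
a two-column TSV (label_id <TAB> name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "BrainMask",
    "AtlasVolume",
    "SpatialMap",
    "StructuralConnectivity",
    "load_mask",
    "load_atlas",
    "vectorize",
    "devectorize",
    "read_connectivity",
    "write_connectivity",
    "save_component_maps",
    "load_component_maps",
]

#: Threshold above which a (possibly probabilistic) mask voxel counts as inside.
MASK_BINARIZE_THRESHOLD = 0.5


class EmptyMaskError(ValueError):
    """Raised when a mask contains no voxels."""


@dataclass(frozen=True)
class BrainMask:
    """A binary voxel domain (e.g. gray matter or white matter).

    Attributes
    ----------
    grid : (nx, ny, nz) bool ndarray
        Inclusion indicator. Immutable after construction.
    affine : (4, 4) float ndarray
        Voxel-to-world transform in mm.
    """

    grid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 3:
            raise ValueError(f"mask grid must be 3-D, got ndim={grid.ndim}")
        if not grid.any():
            raise EmptyMaskError("mask contains no voxels")
        grid = grid.copy()
        grid.setflags(write=False)
        affine = np.array(self.affine, dtype=float)
        affine.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    @property
    def flat_indices(self) -> np.ndarray:
        """Linear (Fortran-order) indices of the masked voxels, ascending."""
        return np.flatnonzero(self.grid.ravel(order="F"))

    @classmethod
    def full(cls, shape: tuple[int, int, int], affine: np.ndarray | None = None) -> "BrainMask":
        """An all-inclusive mask over ``shape`` (used by the simulator)."""
        return cls(np.ones(shape, dtype=bool), np.eye(4) if affine is None else affine)


@dataclass(frozen=True)
class SpatialMap:
    """Values over the masked voxels, in canonical order."""

    values: np.ndarray
    mask: BrainMask

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size != self.mask.n_voxels:
            raise ValueError(
                f"map length {values.size} does not match mask n_voxels {self.mask.n_voxels}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("spatial map contains non-finite values")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class AtlasVolume:
    """Labeled volume (0 = background) plus a label-id -> region-name table."""

    labels: np.ndarray
    names: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("atlas labels must be 3-D")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.allclose(labels, np.round(labels)):
                raise ValueError("atlas labels must be integer-valued")
            labels = np.round(labels).astype(int)
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"atlas labels without names: {sorted(missing)}")
        labels = labels.copy()
        labels.setflags(write=False)
        object.__setattr__(self, "labels", labels)


@dataclass
class StructuralConnectivity:
    """A gray-voxel x white-voxel nonnegative fiber-count matrix."""

    matrix: np.ndarray | sp.spmatrix
    row_mask: BrainMask
    col_mask: BrainMask
    subject_id: str = ""

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.row_mask.n_voxels, self.col_mask.n_voxels):
            raise ValueError(
                f"connectivity shape {m.shape} does not match masks "
                f"({self.row_mask.n_voxels}, {self.col_mask.n_voxels})"
            )
        data = m.data if sp.issparse(m) else np.asarray(m)
        if data.size and data.min() < 0:
            raise ValueError("connectivity entries must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return np.asarray(self.matrix.todense(), dtype=float)
        return np.asarray(self.matrix, dtype=float)

    @property
    def density(self) -> float:
        nnz = self.matrix.nnz if sp.issparse(self.matrix) else np.count_nonzero(self.matrix)
        return nnz / (self.shape[0] * self.shape[1])


def load_mask(path: str | Path, threshold: float = MASK_BINARIZE_THRESHOLD) -> BrainMask:
    """Load a binary (or probabilistic) mask volume.

    Values strictly above ``threshold`` are inside.  Raises on non-3-D
    input and on empty masks.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask volume must be 3-D, got ndim={data.ndim}")
    return BrainMask(grid=data > threshold, affine=img.affine)


def load_atlas(volume_path: str | Path, names_path: str | Path) -> AtlasVolume:
    """Load a labeled atlas NIfTI and its TSV name table (label_id, name)."""
    img = nib.load(str(volume_path))
    labels = np.asanyarray(img.dataobj)
    table = pd.read_csv(names_path, sep="\t", header=None, names=["label", "name"])
    names = {int(row.label): str(row.name) for row in table.itertuples()}
    return AtlasVolume(labels=labels, names=names, affine=img.affine)


def vectorize(volume: np.ndarray, mask: BrainMask) -> SpatialMap:
    """Extract masked voxels of ``volume`` in the canonical order."""
    volume = np.asarray(volume)
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    values = volume.ravel(order="F")[mask.flat_indices]
    return SpatialMap(values=values, mask=mask)


def devectorize(spatial_map: SpatialMap, fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize`; unmasked voxels get ``fill``."""
    mask = spatial_map.mask
    flat = np.full(int(np.prod(mask.shape)), fill, dtype=float)
    flat[mask.flat_indices] = spatial_map.values
    return flat.reshape(mask.shape, order="F")


def vector_to_volume(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Convenience: devectorize a bare vector."""
    return devectorize(SpatialMap(values=np.asarray(values, dtype=float), mask=mask), fill=fill)


def read_connectivity(
    path: str | Path, rows: BrainMask, cols: BrainMask, subject_id: str = ""
) -> StructuralConnectivity:
    """Read a fiber-count matrix from MTX (sparse) or HDF5 (dense).

    The file format is chosen by extension: ``.mtx`` -> MatrixMarket,
    ``.h5``/``.hdf5`` -> HDF5 dataset ``connectivity``.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        matrix = sp.csr_matrix(scipy.io.mmread(str(path)))
    elif path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            matrix = np.asarray(f["connectivity"])
    else:
        raise ValueError(f"unrecognized connectivity format: {path.suffix}")
    return StructuralConnectivity(matrix=matrix, row_mask=rows, col_mask=cols, subject_id=subject_id)


def write_connectivity(sc: StructuralConnectivity, path: str | Path) -> None:
    """Write a connectivity matrix; format chosen by extension (see reader)."""
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(str(path), sp.coo_matrix(sc.matrix))
    elif path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("connectivity", data=sc.to_dense())
    else:
        raise ValueError(f"unrecognized connectivity format: {path.suffix}")


def save_component_maps(
    maps: np.ndarray, mask: BrainMask, path: str | Path, dtype=np.float32
) -> None:
    """Write component maps (n_components x n_voxels) as one 4-D NIfTI."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if maps.shape[1] != mask.n_voxels:
        raise ValueError("map length does not match mask")
    vol4 = np.zeros(mask.shape + (maps.shape[0],), dtype=dtype)
    for k in range(maps.shape[0]):
        vol4[..., k] = vector_to_volume(maps[k], mask)
    nib.save(nib.Nifti1Image(vol4, mask.affine), str(path))


def load_component_maps(path: str | Path, mask: BrainMask) -> np.ndarray:
    """Read back a 4-D component-map file into n_components x n_voxels."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    if data.shape[:3] != mask.shape:
        raise ValueError("component file grid does not match mask")
    return np.stack(
        [vectorize(data[..., k], mask).values for k in range(data.shape[3])], axis=0
    )


def save_mask(mask: BrainMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine), str(path))


def save_atlas(atlas: AtlasVolume, volume_path: str | Path, names_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine), str(volume_path))
    pd.DataFrame(sorted(atlas.names.items())).to_csv(
        names_path, sep="\t", header=False, index=False
    )
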