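"""Volumetric containers, NIfTI I/O, masks and the canonical in-brain voxel index.

All downstream matrices (lesion-seeded connectivity, component maps) are
defined over a single ordered index of in-brain voxels. The ordering is
fixed once and for all: voxel (i, j, k) maps to flat position
``i + dims[0]*j + dims[0]*dims[1]*k`` (x fastest, then y, then z), i.e.
Fortran-order raveling of the 3-D array. Every matrix column in the
package refers to this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "Volume",
    "Mask",
    "Fmri4D",
    "LesionCohort",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "write_mask",
    "binarize",
    "check_grid_compatible",
    "compute_brain_mask",
    "resample_nearest",
    "embed",
]

#: default tolerance (mm) on affine entries when comparing grids
GRID_TOL = 1e-4


class GridMismatchError(ValueError):
    """Two volumes do not share dims/affine within tolerance."""


@dataclass(frozen=True)
class VolumeGrid:
    """Sampling grid: array dims plus the voxel-to-world (MNI mm) affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three positive integers, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def n_total(self) -> int:
        return int(np.prod(self.dims))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n x 3) to world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ homo.T).T[:, :3]


def check_grid_compatible(a: VolumeGrid, b: VolumeGrid, tol: float = GRID_TOL) -> bool:
    """True iff dims are equal and affines agree entrywise within ``tol``."""
    return a.dims == b.dims and bool(np.max(np.abs(a.affine - b.affine)) <= tol)


def _require_same_grid(a: VolumeGrid, b: VolumeGrid, what: str = "volumes") -> None:
    if not check_grid_compatible(a, b):
        raise GridMismatchError(f"{what} are on incompatible grids: {a.dims} vs {b.dims}")


@dataclass
class Volume:
    """A scalar 3-D image on a grid."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid dims {self.grid.dims}"
            )

    def flat(self) -> np.ndarray:
        """Canonical x-fastest flattening of the data."""
        return self.data.ravel(order="F")


@dataclass
class Mask:
    """A binary 3-D image; values strictly 0/1."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        if data.shape != self.grid.dims:
            raise ValueError("mask shape does not match grid dims")
        self.data = data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def flat_index(self) -> np.ndarray:
        """Flat (x-fastest) positions of the 1-voxels, ascending — the canonical index."""
        return np.flatnonzero(self.data.ravel(order="F"))

    def flat(self) -> np.ndarray:
        return self.data.ravel(order="F")

    def intersect(self, other: "Mask") -> "Mask":
        _require_same_grid(self.grid, other.grid, "masks")
        return Mask(self.grid, self.data & other.data)


@dataclass
class Fmri4D:
    """One resting-state session: (x, y, z, t) series on a grid."""

    grid: VolumeGrid
    series: np.ndarray
    tr: float
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 4 or self.series.shape[:3] != self.grid.dims:
            raise ValueError("series must be 4-D matching grid dims")
        if self.series.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        n_bad = int(np.count_nonzero(~np.isfinite(self.series)))
        if n_bad:
            raise ValueError(f"series contains {n_bad} non-finite values")

    @property
    def n_timepoints(self) -> int:
        return int(self.series.shape[3])

    def voxel_series(self, flat_index: np.ndarray) -> np.ndarray:
        """(t, n) matrix of the series at the given canonical flat positions."""
        flat = self.series.reshape(-1, self.n_timepoints, order="F")
        return flat[flat_index].T


@dataclass
class LesionCohort:
    """Ordered per-patient binary lesion masks on one shared grid."""

    patients: list[tuple[str, Mask]]
    grid: VolumeGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.grid is None:
            if not self.patients:
                raise ValueError("empty cohort needs an explicit grid")
            self.grid = self.patients[0][1].grid
        ids = [pid for pid, _ in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("patient ids are not unique")
        for pid, lesion in self.patients:
            _require_same_grid(self.grid, lesion.grid, f"lesion {pid!r} and cohort")
            if lesion.n_voxels < 1:
                raise ValueError(f"lesion {pid!r} is empty")

    @property
    def patient_ids(self) -> list[str]:
        return [pid for pid, _ in self.patients]

    @property
    def lesion_sizes(self) -> np.ndarray:
        return np.array([m.n_voxels for _, m in self.patients])

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def subset(self, ids: list[str]) -> "LesionCohort":
        by_id = dict(self.patients)
        return LesionCohort([(i, by_id[i]) for i in ids], self.grid)


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | Path) -> Volume | Fmri4D:
    """Read a NIfTI file; 3-D data yields a Volume, 4-D an Fmri4D."""
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj).astype(float)
    except Exception as exc:  # noqa: BLE001 - nibabel raises several types
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    n_bad = int(np.count_nonzero(~np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxels")
    grid = VolumeGrid(tuple(data.shape[:3]), np.asarray(img.affine))
    if data.ndim == 4:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        stem = path.name.split(".")[0]
        return Fmri4D(grid, data, tr=tr if tr > 0 else 1.0, subject_id=stem)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3-D or 4-D data, got {data.ndim}-D")
    return Volume(grid, data)


def write_volume(vol: Volume | Fmri4D, path: str | Path) -> None:
    """Write as 32-bit float NIfTI; for 4-D series the TR is stored in the header."""
    if isinstance(vol, Fmri4D):
        img = nib.Nifti1Image(vol.series.astype(np.float32), vol.grid.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr
        img.header.set_zooms(zooms)
    else:
        img = nib.Nifti1Image(vol.data.astype(np.float32), vol.grid.affine)
    nib.save(img, str(path))


def write_mask(mask: Mask, path: str | Path) -> None:
    """Masks are stored as unsigned 8-bit."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Mask construction


def binarize(vol: Volume, threshold: float) -> Mask:
    """1 where data > threshold, 0 elsewhere."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return Mask(vol.grid, (vol.data > threshold).astype(np.uint8))


def compute_brain_mask(fmris: list[Fmri4D]) -> Mask:
    """Intersection of per-subject nonzero-variance support.

    A voxel is in-brain for a subject iff its series is finite with nonzero
    variance in every session of that subject; the cohort mask is the AND
    over subjects. This mirrors taking the common coverage of all healthy
    controls before any connectivity is computed.
    """
    if not fmris:
        raise ValueError("need at least one fMRI run")
    grid = fmris[0].grid
    by_subject: dict[str, np.ndarray] = {}
    for f in fmris:
        _require_same_grid(grid, f.grid, "fMRI runs")
        var = f.series.var(axis=3)
        support = var > 0
        key = f.subject_id
        by_subject[key] = support if key not in by_subject else (by_subject[key] & support)
    common = np.logical_and.reduce(list(by_subject.values()))
    if not common.any():
        raise ValueError("no common brain voxels across subjects")
    return Mask(grid, common.astype(np.uint8))


def resample_nearest(vol: Volume | Mask, target: VolumeGrid) -> Volume | Mask:
    """Nearest-neighbour resampling onto another grid (explicit, never implicit).

    Intended for reference maps delivered on a different grid; binary masks
    stay binary because no interpolation is performed.
    """
    src_grid = vol.grid
    inv = np.linalg.inv(src_grid.affine)
    ii, jj, kk = np.meshgrid(*[np.arange(d) for d in target.dims], indexing="ij")
    tgt_vox = np.c_[ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)]
    src_vox = (inv @ target.affine @ tgt_vox.T).T[:, :3]
    src_idx = np.round(src_vox).astype(int)
    inside = np.all((src_idx >= 0) & (src_idx < np.array(src_grid.dims)), axis=1)
    data_src = vol.data
    out = np.zeros(ii.size, dtype=float)
    out[inside] = data_src[src_idx[inside, 0], src_idx[inside, 1], src_idx[inside, 2]]
    out = out.reshape(target.dims)
    if isinstance(vol, Mask):
        return Mask(target, out.astype(np.uint8))
    return Volume(target, out)


def embed(values: np.ndarray, mask: Mask) -> Volume:
    """Scatter a vector over the mask's canonical flat index into a full volume."""
    values = np.asarray(values, dtype=float)
    idx = mask.flat_index
    if values.shape != idx.shape:
        raise ValueError(f"expected {idx.size} values, got {values.size}")
    flat = np.zeros(mask.grid.n_total)
    flat[idx] = values
    return Volume(mask.grid, flat.reshape(mask.grid.dims, order="F"))
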