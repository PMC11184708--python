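"""Volume, mask, motion-trace and cohort-table I/O plus voxel geometry.

All volumes are NIfTI-1; mm coordinates follow the image affine (RAS+,
0-based voxel indices).  In-mask voxels are always enumerated in a single
canonical order: ascending linear index with the *first* axis fastest
(Fortran order), so that every module sees the same voxel sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DimensionalityError, FormatError, GeometryError, ValidationError

GROUPS = ("LSS", "RSS", "HC")
GENDERS = ("male", "female")

#: (column, min, max) instrument ranges enforced on patient scores.
SCORE_RANGES = {"fma_ue": (0.0, 66.0), "fma_le": (0.0, 34.0), "mbi_c": (0.0, 100.0)}

#: Columns of the tab-separated cohort table, in canonical order.
COHORT_COLUMNS = [
    "id", "group", "age", "gender", "education", "head_motion",
    "lesion_volume", "duration", "fma_ue", "fma_le", "mbi_c",
]

_PATIENT_ONLY = ["lesion_volume", "duration", "fma_ue", "fma_le", "mbi_c"]


@dataclass(frozen=True, eq=False)
class VolumeGrid:
    """A voxel lattice plus the affine mapping voxel indices to mm."""

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "affine", affine)
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise GeometryError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "dims", dims)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Voxel edge lengths in mm (column norms of the linear part)."""
        return tuple(float(np.linalg.norm(self.affine[:3, k])) for k in range(3))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)

    def index_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        hom = np.hstack([ijk, np.ones((ijk.shape[0], 1))])
        return (self.affine @ hom.T).T[:, :3]


@dataclass
class Series4D:
    """One subject's 4D signal: ``data`` has shape ``(*grid.dims, n_volumes)``."""

    grid: VolumeGrid
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise DimensionalityError(f"series data must be 4D, got ndim={self.data.ndim}")
        if self.data.shape[:3] != self.grid.dims:
            raise GeometryError(
                f"data shape {self.data.shape[:3]} does not match grid dims {self.grid.dims}"
            )
        if self.n_volumes < 2:
            raise DimensionalityError("a series needs at least 2 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("series data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Binary analysis mask on a grid."""

    grid: VolumeGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        if self.inside.shape != self.grid.dims:
            raise GeometryError(
                f"mask shape {self.inside.shape} does not match grid dims {self.grid.dims}"
            )
        if int(self.inside.sum()) < 2:
            raise ValidationError("mask must contain at least 2 voxels")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())


def mask_indices(mask: BrainMask) -> np.ndarray:
    """(M, 3) voxel indices of in-mask voxels in canonical (first-axis-fastest) order."""
    flat = np.flatnonzero(mask.inside.reshape(-1, order="F"))
    i, j, k = np.unravel_index(flat, mask.grid.dims, order="F")
    return np.column_stack([i, j, k]).astype(np.intp)


def voxel_coordinates(grid: VolumeGrid, mask: BrainMask) -> np.ndarray:
    """(M, 3) mm coordinates of in-mask voxels in canonical order."""
    if not grid.matches(mask.grid):
        raise GeometryError("grid and mask are defined on different grids")
    return grid.index_to_mm(mask_indices(mask))


def extract_series(series: Series4D, mask: BrainMask) -> np.ndarray:
    """(M, T) time series of in-mask voxels in canonical order."""
    if not series.grid.matches(mask.grid):
        raise GeometryError("series and mask are defined on different grids")
    idx = mask_indices(mask)
    return series.data[idx[:, 0], idx[:, 1], idx[:, 2], :]


def insert_map(values: np.ndarray, mask: BrainMask, fill: float = 0.0) -> np.ndarray:
    """Scatter an (M,) in-mask vector back to a full 3D volume."""
    values = np.asarray(values)
    if values.shape != (mask.n_inside,):
        raise GeometryError(
            f"expected {mask.n_inside} in-mask values, got shape {values.shape}"
        )
    out = np.full(mask.grid.dims, fill, dtype=float)
    idx = mask_indices(mask)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path):
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return img, data


def read_series(path, tr_seconds: float | None = None) -> Series4D:
    """Read a 4D NIfTI image.

    The TR is taken from the header's 4th zoom unless overridden; a header
    TR of 0 falls back to 2.0 s.
    """
    img, data = _load_nifti(path)
    if data.ndim != 4:
        raise DimensionalityError(f"{path}: expected a 4D image, got ndim={data.ndim}")
    grid = VolumeGrid(dims=data.shape[:3], affine=img.affine)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Series4D(grid=grid, data=data.astype(float), tr_seconds=tr_seconds)


def write_series(series: Series4D, path) -> None:
    img = nib.Nifti1Image(series.data, series.grid.affine)
    img.header.set_zooms((*series.grid.voxel_size, series.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    img, data = _load_nifti(path)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D mask, got ndim={data.ndim}")
    grid = VolumeGrid(dims=data.shape, affine=img.affine)
    return BrainMask(grid=grid, inside=data > 0)


def write_mask(mask: BrainMask, path) -> None:
    nib.save(nib.Nifti1Image(mask.inside.astype(np.uint8), mask.grid.affine), str(path))


def read_volume(path) -> tuple[VolumeGrid, np.ndarray]:
    """Read a 3D scalar volume (e.g. an FCD map or overlap map)."""
    img, data = _load_nifti(path)
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return VolumeGrid(dims=data.shape, affine=img.affine), data.astype(float)


def write_volume(volume: np.ndarray, grid: VolumeGrid, path) -> None:
    if volume.shape != grid.dims:
        raise GeometryError("volume shape does not match grid dims")
    nib.save(nib.Nifti1Image(np.asarray(volume), grid.affine), str(path))


# ---------------------------------------------------------------------------
# Motion traces
# ---------------------------------------------------------------------------

def read_motion(path) -> np.ndarray:
    """Read a plain-text 6-column motion trace (3 translations mm, 3 rotations deg)."""
    trace = np.loadtxt(str(path), ndmin=2)
    if trace.shape[1] != 6:
        raise FormatError(f"{path}: motion trace must have 6 columns, got {trace.shape[1]}")
    return trace.astype(float)


def write_motion(trace: np.ndarray, path) -> None:
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise FormatError("motion trace must be (n_volumes, 6)")
    np.savetxt(str(path), trace, fmt="%.8f")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Typed per-subject table of group labels, covariates and clinical scores.

    Patient-only fields (lesion volume, duration, scores) are NaN for HC rows.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in ["id", "group", "age", "gender"] if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing required columns: {missing}")
        for col in COHORT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["id"] = df["id"].astype(str)
        df["group"] = df["group"].astype(str)
        df["gender"] = df["gender"].astype(str)
        for col in COHORT_COLUMNS[2:]:
            if col != "gender":
                df[col] = pd.to_numeric(df[col], errors="coerce")
        self.frame = df[COHORT_COLUMNS].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.frame
        for row in df.itertuples():
            if row.group not in GROUPS:
                raise ValidationError(
                    f"row {row.Index} (id={row.id}): unknown group {row.group!r}"
                )
            if row.gender not in GENDERS:
                raise ValidationError(
                    f"row {row.Index} (id={row.id}): unknown gender {row.gender!r}"
                )
            for col, (lo, hi) in SCORE_RANGES.items():
                val = getattr(row, col)
                if pd.notna(val) and not (lo <= val <= hi):
                    raise ValidationError(
                        f"row {row.Index} (id={row.id}): {col}={val} outside [{lo}, {hi}]"
                    )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> pd.Series:
        return self.frame["group"]

    def subset(self, groups) -> "CohortTable":
        keep = self.frame["group"].isin(list(groups))
        return CohortTable(self.frame.loc[keep].reset_index(drop=True))

    def patients(self) -> "CohortTable":
        return self.subset(["LSS", "RSS"])


def read_cohort(path) -> CohortTable:
    try:
        df = pd.read_csv(str(path), sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot read cohort table {path}: {exc}") from exc
    return CohortTable(df)


def write_cohort(table: CohortTable, path) -> None:
    table.frame.to_csv(str(path), sep="\t", index=False, float_format="%.6g")
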