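"""Distance-dependent functional connectivity density (FCD) mapping.

For every in-mask voxel i the global FCD is the mean absolute Pearson
correlation with all other in-mask voxels; the short-/long-range maps
restrict the mean to voxel pairs whose Euclidean mm distance is at most /
strictly above the distance criterion (default 12 mm; 6 and 18 mm offered
for validation).  Maps are the *weighted* variant: no correlation threshold
is applied.  Raw maps are Fisher r-to-z transformed after clipping at
1 - eps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError, ValidationError
from .io_formats import (BrainMask, Series4D, insert_map, mask_indices,
                         voxel_coordinates)

EPSILON = 1e-7


@dataclass(frozen=True)
class DistanceConfig:
    """Distance criterion splitting short-range (D <= d_c) from long-range
    (D > d_c) connections."""

    criterion_mm: float = 12.0
    epsilon: float = EPSILON

    def __post_init__(self) -> None:
        if self.criterion_mm <= 0:
            raise ParameterError("distance criterion must be positive")
        if not (0 < self.epsilon < 1):
            raise ParameterError("epsilon must be in (0, 1)")


@dataclass
class FCDMaps:
    """Per-subject FCD volumes (zeros outside the mask)."""

    mask: BrainMask
    config: DistanceConfig
    g_raw: np.ndarray
    s_raw: np.ndarray
    l_raw: np.ndarray
    g_z: np.ndarray = field(repr=False, default=None)
    s_z: np.ndarray = field(repr=False, default=None)
    l_z: np.ndarray = field(repr=False, default=None)
    n_short: np.ndarray = field(repr=False, default=None)
    n_long: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"g_raw": self.g_raw, "s_raw": self.s_raw, "l_raw": self.l_raw,
                "g_z": self.g_z, "s_z": self.s_z, "l_z": self.l_z}


def pair_distance(c_i, c_j) -> float:
    """Euclidean mm distance between two coordinate triples."""
    c_i = np.asarray(c_i, dtype=float)
    c_j = np.asarray(c_j, dtype=float)
    if not (np.all(np.isfinite(c_i)) and np.all(np.isfinite(c_j))):
        raise ParameterError("coordinates must be finite")
    return float(np.sqrt(((c_i - c_j) ** 2).sum()))


def fisher_z(v, epsilon: float = EPSILON):
    """Fisher r-to-z of a non-negative correlation magnitude, clipping at
    1 - epsilon so that |r| = 1 stays finite."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ParameterError("fisher_z input must lie in [0, 1]")
    out = np.arctanh(np.minimum(arr, 1.0 - epsilon))
    return float(out) if np.isscalar(v) else out


def _standardized_timeseries(series: Series4D, mask: BrainMask):
    """Return (X, keep_mask) where X rows are unit-norm centered series for
    in-mask voxels with nonzero variance; X @ X.T is the correlation matrix."""
    from .io_formats import extract_series

    ts = extract_series(series, mask)            # (M, T)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    keep = norms > 0
    if not keep.all():
        n_dropped = int((~keep).sum())
        warnings.warn(f"dropping {n_dropped} zero-variance voxel(s) from the mask",
                      RuntimeWarning, stacklevel=3)
        if keep.sum() < 2:
            raise ValidationError("all in-mask voxels have zero variance")
    ts = ts[keep] / norms[keep][:, None]
    return ts, keep


#: Cache of short-pair boolean matrices keyed by (dims, affine, mask,
#: criterion); entries are O(M^2) bools so only small masks are cached.
_SHORT_CACHE: dict = {}
_SHORT_CACHE_MAX_VOXELS = 4096


def _short_pairs(mask: BrainMask, criterion_mm: float) -> np.ndarray | None:
    """(M, M) boolean matrix of short-range pairs (self excluded), cached for
    small masks; None when the mask is too large to cache."""
    m = mask.n_inside
    if m > _SHORT_CACHE_MAX_VOXELS:
        return None
    key = (mask.grid.dims, mask.grid.affine.tobytes(),
           mask.inside.tobytes(), float(criterion_mm))
    cached = _SHORT_CACHE.get(key)
    if cached is None:
        coords = voxel_coordinates(mask.grid, mask)
        sq = (coords ** 2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (coords @ coords.T)
        cached = d2 <= float(criterion_mm) ** 2
        np.fill_diagonal(cached, False)
        if len(_SHORT_CACHE) > 8:
            _SHORT_CACHE.clear()
        _SHORT_CACHE[key] = cached
    return cached


def compute_fcd(series: Series4D, mask: BrainMask,
                config: DistanceConfig = DistanceConfig(),
                block_size: int = 2048) -> FCDMaps:
    """Compute gFCD/sFCD/lFCD maps, blocked over voxels.

    Results are independent of ``block_size``.  Zero-variance in-mask voxels
    are dropped from the effective mask with a warning.
    """
    if not series.grid.matches(mask.grid):
        raise GeometryError("series and mask grids differ")
    X, keep = _standardized_timeseries(series, mask)
    if not keep.all():
        idx = mask_indices(mask)[keep]
        inside = np.zeros(mask.grid.dims, dtype=bool)
        inside[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        mask = BrainMask(grid=mask.grid, inside=inside)
    coords = voxel_coordinates(mask.grid, mask)  # (M, 3)
    m = X.shape[0]
    d2_crit = float(config.criterion_mm) ** 2
    short_full = _short_pairs(mask, config.criterion_mm)

    sum_all = np.empty(m)
    sum_short = np.empty(m)
    n_short = np.empty(m, dtype=np.int64)
    sq = (coords ** 2).sum(axis=1)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        r_abs = np.abs(X[start:stop] @ X.T)       # (b, M)
        np.clip(r_abs, 0.0, 1.0, out=r_abs)       # guard fp overshoot
        rows = np.arange(start, stop)
        if short_full is not None:
            short = short_full[start:stop]
        else:
            d2 = (sq[rows][:, None] + sq[None, :]
                  - 2.0 * (coords[rows] @ coords.T))  # squared mm distances
            short = d2 <= d2_crit
            short[np.arange(stop - start), rows] = False  # exclude self
        sum_all[rows] = r_abs.sum(axis=1) - 1.0       # minus |r_ii| = 1
        sum_short[rows] = (r_abs * short).sum(axis=1)
        n_short[rows] = short.sum(axis=1)

    n_long = (m - 1) - n_short
    g_raw = sum_all / (m - 1)
    with np.errstate(invalid="ignore"):
        s_raw = np.where(n_short > 0, sum_short / np.maximum(n_short, 1), 0.0)
        l_raw = np.where(n_long > 0, (sum_all - sum_short) / np.maximum(n_long, 1), 0.0)
    np.clip(g_raw, 0.0, 1.0, out=g_raw)
    np.clip(s_raw, 0.0, 1.0, out=s_raw)
    np.clip(l_raw, 0.0, 1.0, out=l_raw)

    eps = config.epsilon
    return FCDMaps(
        mask=mask, config=config,
        g_raw=insert_map(g_raw, mask), s_raw=insert_map(s_raw, mask),
        l_raw=insert_map(l_raw, mask),
        g_z=insert_map(fisher_z(g_raw, eps), mask),
        s_z=insert_map(fisher_z(s_raw, eps), mask),
        l_z=insert_map(fisher_z(l_raw, eps), mask),
        n_short=insert_map(n_short.astype(float), mask).astype(np.int64),
        n_long=insert_map(n_long.astype(float), mask).astype(np.int64),
    )


def whole_brain_mean(volume: np.ndarray, mask: BrainMask) -> float:
    """Mean of a map over in-mask voxels."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != mask.grid.dims:
        raise GeometryError("map shape does not match mask grid")
    return float(volume[mask.inside].mean())
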