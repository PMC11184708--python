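"""Stationary Gaussian random-field machinery: residual-based smoothness
estimation, resel counting, and cluster-level family-wise-error correction.

The stat map is probability-transformed to an equivalent Gaussian field,
thresholded at the cluster-defining voxel p, and clusters (26-connectivity)
are assigned FWE p-values from the expected-cluster-count / cluster-extent
tail approximation:

    p_FWE(k) = 1 - exp(-E[m] * P(n >= k)),   P(n >= k) = exp(-beta k^(2/3))

with E[m] from the Euler-characteristic densities over the mask's resel
counts and beta = (Gamma(5/2) * E[m] / E[N])^(2/3).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gamma as gamma_fn

import numpy as np
from scipy import ndimage, stats

from ..errors import ParameterError
from ..io_formats import BrainMask, VolumeGrid, insert_map, mask_indices
from .voxelwise import StatMap

_LN2x4 = 4.0 * np.log(2.0)


@dataclass
class SmoothnessEstimate:
    fwhm_mm: tuple[float, float, float]
    fwhm_vox: tuple[float, float, float]
    resels: float
    resel_counts: tuple[float, float, float, float]  # R0..R3

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.fwhm_mm)) or any(f <= 0 for f in self.fwhm_mm):
            raise ParameterError(f"non-positive smoothness estimate: {self.fwhm_mm}")


@dataclass
class Cluster:
    voxel_indices: np.ndarray      # (k, 3) grid indices
    size: int
    peak_stat: float
    peak_mm: tuple[float, float, float]
    p_fwe: float
    sign: int = 1                  # -1 for negative-tail t clusters


def _axis_pairs(mask3d: np.ndarray, axis: int):
    """Boolean volume of voxels whose +1 neighbour along ``axis`` is in-mask."""
    a = mask3d
    b = np.roll(mask3d, -1, axis=axis)
    pair = a & b
    sl = [slice(None)] * 3
    sl[axis] = slice(-1, None)
    pair[tuple(sl)] = False       # do not wrap around
    return pair


def estimate_smoothness(residuals: np.ndarray, mask: BrainMask) -> SmoothnessEstimate:
    """Per-axis FWHM from the spatial derivatives of variance-normalized
    residual maps.

    ``residuals`` is (n_maps, V) in canonical in-mask order (as returned by
    the voxelwise fits).  FWHM_k = sqrt(4 ln 2 / lambda_k) where lambda_k is
    the mean squared derivative of the unit-variance residual field along
    axis k (in voxel units).
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.ndim != 2 or resid.shape[0] < 2:
        raise ParameterError("need >= 2 residual maps of shape (n_maps, V)")
    ssq = np.sqrt((resid ** 2).sum(axis=0))
    u = resid / np.where(ssq > 0, ssq, 1.0)   # unit norm across maps, per voxel

    dims = mask.grid.dims
    idx = mask_indices(mask)
    vol = np.zeros((resid.shape[0], *dims))
    vol[:, idx[:, 0], idx[:, 1], idx[:, 2]] = u

    fwhm_vox = []
    for axis in range(3):
        pairs = _axis_pairs(mask.inside, axis)
        if not pairs.any():
            fwhm_vox.append(float(dims[axis]))   # flat axis: treat as unsmooth
            continue
        diff = np.roll(vol, -1, axis=axis + 1) - vol
        # per voxel the normalized residuals have unit sum of squares across
        # maps, so summing squared derivatives over maps estimates the
        # derivative variance of a unit-variance field directly
        lam = max(float((diff[:, pairs] ** 2).sum() / pairs.sum()), 1e-12)
        fwhm_vox.append(float(np.sqrt(_LN2x4 / lam)))
    voxel_size = mask.grid.voxel_size
    fwhm_mm = tuple(f * v for f, v in zip(fwhm_vox, voxel_size))
    counts = resel_counts(mask, tuple(fwhm_vox))
    return SmoothnessEstimate(fwhm_mm=fwhm_mm, fwhm_vox=tuple(fwhm_vox),
                              resels=counts[3], resel_counts=counts)


def resel_counts(mask: BrainMask, fwhm_vox: tuple[float, float, float]
                 ) -> tuple[float, float, float, float]:
    """Worsley-style resel counts R0..R3 of a voxel mask.

    Counts points, edges, faces and cubes of the in-mask lattice and scales
    by the per-axis resel sizes (voxels / FWHM)."""
    m = mask.inside
    rx, ry, rz = (1.0 / f for f in fwhm_vox)
    ex = _axis_pairs(m, 0)
    ey = _axis_pairs(m, 1)
    ez = _axis_pairs(m, 2)
    fxy = ex & np.roll(ex, -1, axis=1) & _axis_pairs(m, 1)
    fxz = ex & np.roll(ex, -1, axis=2) & _axis_pairs(m, 2)
    fyz = ey & np.roll(ey, -1, axis=2) & _axis_pairs(m, 2)
    cube = fxy & np.roll(fxy, -1, axis=2) & _axis_pairs(m, 2)
    p = float(m.sum())
    ex, ey, ez = float(ex.sum()), float(ey.sum()), float(ez.sum())
    fxy, fxz, fyz = float(fxy.sum()), float(fxz.sum()), float(fyz.sum())
    c = float(cube.sum())
    r0 = p - (ex + ey + ez) + (fxy + fxz + fyz) - c
    r1 = (ex * rx + ey * ry + ez * rz) - (fxy * (rx + ry) + fxz * (rx + rz)
                                          + fyz * (ry + rz)) \
        + c * (rx + ry + rz)
    r2 = fxy * rx * ry + fxz * rx * rz + fyz * ry * rz \
        - c * (rx * ry + rx * rz + ry * rz)
    r3 = c * rx * ry * rz
    return (r0, r1, r2, r3)


def ec_densities(u: float) -> tuple[float, float, float, float]:
    """Euler-characteristic densities rho_0..rho_3 of a unit Gaussian field
    thresholded at u."""
    e = np.exp(-u * u / 2.0)
    rho0 = float(stats.norm.sf(u))
    rho1 = np.sqrt(_LN2x4) / (2.0 * np.pi) * e
    rho2 = _LN2x4 / (2.0 * np.pi) ** 1.5 * u * e
    rho3 = _LN2x4 ** 1.5 / (2.0 * np.pi) ** 2 * (u * u - 1.0) * e
    return (rho0, float(rho1), float(rho2), float(rho3))


def expected_clusters(u: float, counts: tuple[float, float, float, float]) -> float:
    """Expected number of suprathreshold clusters E[m] at Gaussian threshold u."""
    rho = ec_densities(u)
    return float(max(sum(r * d for r, d in zip(counts, rho)), 1e-300))


def cluster_extent_pfwe(k: int, u: float, n_mask_voxels: int,
                        counts: tuple[float, float, float, float]) -> float:
    """Cluster-level FWE p for an extent of k voxels at Gaussian threshold u."""
    em = expected_clusters(u, counts)
    en = n_mask_voxels * float(stats.norm.sf(u))  # expected suprathreshold voxels
    if en <= 0:
        return 1.0
    beta = (gamma_fn(2.5) * em / en) ** (2.0 / 3.0)
    p_tail = np.exp(-beta * float(k) ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_tail))


def _to_z(stat: StatMap) -> np.ndarray:
    """Probability-transform a stat map to an equivalent Gaussian map."""
    if stat.kind == "F":
        p = stats.f.sf(stat.values, *stat.df)
        return stats.norm.isf(np.clip(p, 1e-300, 1.0))
    # t: signed transform through the one-tailed p
    p = stats.t.sf(np.abs(stat.values), stat.df[0])
    z = stats.norm.isf(np.clip(p, 1e-300, 1.0))
    return np.sign(stat.values) * z


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _label_clusters(excursion: np.ndarray):
    labels, n = ndimage.label(excursion, structure=_CONN26)
    return labels, n


def grf_cluster_correct(stat: StatMap, mask: BrainMask,
                        smoothness: SmoothnessEstimate,
                        voxel_p: float = 0.01, cluster_p: float = 0.05,
                        two_tailed: bool | None = None) -> list[Cluster]:
    """GRF cluster-corrected inference on a stat map.

    F maps are thresholded in the upper tail at ``voxel_p``; t maps, when
    ``two_tailed`` (the default for t), use ``voxel_p / 2`` per tail with
    positive and negative excursions clustered separately and the doubled
    expected cluster count entering the FWE probability.  Surviving clusters
    (FWE p < ``cluster_p``) are returned sorted by decreasing size.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ParameterError("voxel_p and cluster_p must lie in (0, 1)")
    if not all(np.isfinite(smoothness.fwhm_vox)):
        raise ParameterError("non-finite smoothness estimate")
    if two_tailed is None:
        two_tailed = stat.kind == "t"
    if stat.kind == "F" and two_tailed:
        two_tailed = False          # F is one-sided by construction

    tail_p = voxel_p / 2.0 if two_tailed else voxel_p
    u = float(stats.norm.isf(tail_p))
    z = _to_z(stat)
    zvol = insert_map(z, mask, fill=-np.inf)
    n_vox = mask.n_inside
    counts = smoothness.resel_counts
    n_tails = 2 if two_tailed else 1

    clusters: list[Cluster] = []
    stat_vol = insert_map(stat.values, mask, fill=np.nan)
    tails = [(1, zvol >= u)]
    if two_tailed:
        tails.append((-1, np.where(np.isfinite(zvol), -zvol, -np.inf) >= u))
    for sign, excursion in tails:
        labels, n = _label_clusters(excursion & mask.inside)
        for lab in range(1, n + 1):
            where = np.argwhere(labels == lab)
            k = where.shape[0]
            em = expected_clusters(u, counts) * n_tails
            en = n_vox * float(stats.norm.sf(u)) * n_tails
            beta = (gamma_fn(2.5) * em / max(en, 1e-300)) ** (2.0 / 3.0)
            p_fwe = float(1.0 - np.exp(-em * np.exp(-beta * k ** (2.0 / 3.0))))
            if p_fwe >= cluster_p:
                continue
            stats_here = sign * zvol[where[:, 0], where[:, 1], where[:, 2]]
            peak_row = where[int(np.argmax(stats_here))]
            peak_mm = tuple(mask.grid.index_to_mm(peak_row)[0])
            # report the peak of the original statistic, not the z transform
            peak_stat = float(stat_vol[tuple(peak_row)])
            clusters.append(Cluster(voxel_indices=where, size=k,
                                    peak_stat=peak_stat, peak_mm=peak_mm,
                                    p_fwe=p_fwe, sign=sign))
    clusters.sort(key=lambda c: -c.size)
    return clusters


def cluster_mask(clusters: list[Cluster], grid: VolumeGrid) -> np.ndarray:
    """Boolean volume marking all voxels of the given clusters."""
    out = np.zeros(grid.dims, dtype=bool)
    for c in clusters:
        out[c.voxel_indices[:, 0], c.voxel_indices[:, 1], c.voxel_indices[:, 2]] = True
    return out
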