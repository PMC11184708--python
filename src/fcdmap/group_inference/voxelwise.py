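"""Voxelwise GLM: ANCOVA F maps, covariate-adjusted post-hoc t maps with
Cohen's d, and seed-based functional connectivity maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..errors import DesignError, GeometryError, ValidationError
from ..fcd_core import EPSILON
from ..io_formats import BrainMask, Series4D, extract_series, insert_map
from .design import Design, build_design


@dataclass
class StatMap:
    """A voxelwise statistic map (values are in-mask vectors, canonical order)."""

    kind: str                       # "F" or "t"
    values: np.ndarray              # (V,)
    df: tuple

    def p_values(self) -> np.ndarray:
        if self.kind == "F":
            return stats.f.sf(self.values, *self.df)
        return 2.0 * stats.t.sf(np.abs(self.values), self.df[0])


def _fit(design_matrix: np.ndarray, maps: np.ndarray):
    """OLS fit of all voxels at once: returns (beta, residuals, rss)."""
    beta, *_ = np.linalg.lstsq(design_matrix, maps, rcond=None)
    resid = maps - design_matrix @ beta
    return beta, resid, (resid ** 2).sum(axis=0)


def ancova_f_map(subject_maps: np.ndarray, design: Design):
    """Voxelwise F test of the group factor adjusted for covariates.

    ``subject_maps`` is (N, V).  Returns (StatMap, residual maps (N, V)) —
    the residuals of the full model, for smoothness estimation.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != design.n:
        raise DesignError("subject_maps must be (n_subjects, n_voxels)")
    full = design.matrix
    reduced = np.delete(full, design.group_columns, axis=1)
    df1 = len(design.group_columns)
    df2 = design.n - np.linalg.matrix_rank(full)
    if df1 < 1 or df2 < 1:
        raise DesignError("insufficient degrees of freedom")
    _, resid, rss_full = _fit(full, maps)
    _, _, rss_reduced = _fit(reduced, maps)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_reduced - rss_full) / df1) / (rss_full / df2)
    f = np.where(np.isfinite(f), np.maximum(f, 0.0), 0.0)
    return StatMap(kind="F", values=f, df=(df1, df2)), resid


def posthoc_pairwise(subject_maps: np.ndarray, table, pair,
                     covariates=("age", "gender", "education", "head_motion")):
    """Covariate-adjusted two-sample t map for ``pair = (group_a, group_b)``
    plus the Cohen's d map (``d = t * sqrt(1/n_a + 1/n_b)``; sign is
    group_a minus group_b).

    ``subject_maps`` rows must correspond to ``table`` rows; only the pair's
    subjects are used.
    """
    group_a, group_b = pair
    frame = table.frame
    keep = frame["group"].isin([group_a, group_b]).to_numpy()
    sub = table.subset([group_a, group_b])
    maps = np.asarray(subject_maps, dtype=float)[keep]
    design = build_design(sub, covariates=covariates)
    # the indicator codes membership of whichever pair group sorts first in
    # the canonical order; flip the sign if that is not group_a
    col = design.group_columns[0]
    indicator_group = design.columns[col].removeprefix("group_")
    sign = 1.0 if indicator_group == group_a else -1.0

    x = design.matrix
    df = design.n - np.linalg.matrix_rank(x)
    beta, resid, rss = _fit(x, maps)
    xtx_inv = np.linalg.inv(x.T @ x)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / df
        se = np.sqrt(sigma2 * xtx_inv[col, col])
        t = sign * beta[col] / se
    t = np.where(np.isfinite(t), t, 0.0)
    n_a = int((sub.frame["group"] == group_a).sum())
    n_b = int((sub.frame["group"] == group_b).sum())
    d = t * np.sqrt(1.0 / n_a + 1.0 / n_b)
    return StatMap(kind="t", values=t, df=(df,)), d


def seed_fc(series: Series4D, mask: BrainMask, seed_mask: BrainMask,
            epsilon: float = EPSILON) -> np.ndarray:
    """Fisher-z map of the Pearson correlation between the seed-mean time
    series and every in-mask voxel (signed; |r| clipped at 1 - epsilon).
    Returns a full 3D volume, zeros outside the mask."""
    if not series.grid.matches(mask.grid) or not series.grid.matches(seed_mask.grid):
        raise GeometryError("series, mask and seed must share a grid")
    if not mask.inside[seed_mask.inside].all():
        raise GeometryError("seed region must lie within the analysis mask")
    seed_ts = extract_series(series, seed_mask).mean(axis=0)
    seed_ts = seed_ts - seed_ts.mean()
    norm = np.linalg.norm(seed_ts)
    if norm == 0:
        raise ValidationError("seed mean time series has zero variance")
    seed_ts /= norm
    ts = extract_series(series, mask)
    ts = ts - ts.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ts, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ts @ seed_ts / np.where(norms > 0, norms, 1.0)
    r = np.clip(np.where(norms > 0, r, 0.0), -1.0 + epsilon, 1.0 - epsilon)
    return insert_map(np.arctanh(r), mask)
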