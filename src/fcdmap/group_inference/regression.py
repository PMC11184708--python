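"""Clinical-score regression, Benjamini-Hochberg FDR, cluster feature
extraction and longitudinal change concordance."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import DesignError, GeometryError, ParameterError
from .rft import Cluster


@dataclass
class RegressionRow:
    """One (region-feature, clinical score) association."""

    feature_label: str
    score_label: str
    beta: float
    r_squared: float
    t: float
    p: float
    p_adjusted: float | None = None


def clinical_regression(feature: np.ndarray, score: np.ndarray,
                        covariates: pd.DataFrame | np.ndarray | None = None,
                        feature_label: str = "feature",
                        score_label: str = "score") -> RegressionRow:
    """OLS of score on feature plus covariates; reports the feature's beta,
    t and p, and the full model's R^2."""
    feature = np.asarray(feature, dtype=float)
    score = np.asarray(score, dtype=float)
    n = feature.shape[0]
    if score.shape[0] != n:
        raise DesignError("feature and score length mismatch")
    cols = [np.ones(n), feature]
    if covariates is not None:
        cov = (covariates.to_numpy(dtype=float)
               if isinstance(covariates, pd.DataFrame)
               else np.asarray(covariates, dtype=float))
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise DesignError("covariate row count mismatch")
        cols.append(cov)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise DesignError("regression design is rank-deficient")
    df = n - rank
    if df < 1:
        raise DesignError("no residual degrees of freedom")
    beta, *_ = np.linalg.lstsq(x, score, rcond=None)
    resid = score - x @ beta
    rss = float(resid @ resid)
    tss = float(((score - score.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    xtx_inv = np.linalg.inv(x.T @ x)
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(beta[1] / se) if se > 0 else np.inf * np.sign(beta[1])
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return RegressionRow(feature_label=feature_label, score_label=score_label,
                         beta=float(beta[1]), r_squared=float(np.clip(r2, 0.0, 1.0)),
                         t=t, p=p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p_values must be a non-empty 1D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def adjust_family(rows: list[RegressionRow]) -> list[RegressionRow]:
    """Attach BH-adjusted p-values across a family of regression rows."""
    adj = bh_fdr([row.p for row in rows])
    for row, a in zip(rows, adj):
        row.p_adjusted = float(a)
    return rows


def extract_cluster_feature(volume: np.ndarray, cluster: Cluster,
                            statistic: str = "mean") -> float:
    """Aggregate a subject's map over a cluster (mean by default; 'peak'
    takes the value at the cluster peak)."""
    volume = np.asarray(volume, dtype=float)
    idx = cluster.voxel_indices
    if idx.shape[0] == 0:
        raise GeometryError("empty cluster")
    if np.any(idx >= np.asarray(volume.shape)) or np.any(idx < 0):
        raise GeometryError("cluster indices outside the map grid")
    values = volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    if statistic == "mean":
        return float(values.mean())
    if statistic == "peak":
        return float(values[int(np.argmax(np.abs(values)))])
    raise ParameterError(f"unknown cluster statistic {statistic!r}")


def change_concordance(pre_scores, post_scores, pre_features, post_features,
                       score_direction: int = 1,
                       feature_direction: int = -1) -> float:
    """Fraction of patients whose score changes in ``score_direction`` AND
    whose feature changes in ``feature_direction`` (default: score up,
    feature down)."""
    arrays = [np.asarray(a, dtype=float)
              for a in (pre_scores, post_scores, pre_features, post_features)]
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays) or n == 0:
        raise ParameterError("pre/post rows must be non-empty and paired")
    d_score = (arrays[1] - arrays[0]) * score_direction
    d_feat = (arrays[3] - arrays[2]) * feature_direction
    return float(((d_score > 0) & (d_feat > 0)).mean())
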