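"""Summary-statistic demographic tests and the design power computation.

These operate on printed group summaries (means, SDs, counts) so published
demographic tables can be recomputed without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ParameterError
from ..io_formats import CohortTable


def summary_anova(means, sds, ns) -> tuple[float, float]:
    """One-way fixed-effects ANOVA from per-group summaries."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    k = means.size
    if k < 2 or sds.size != k or ns.size != k:
        raise ParameterError("need matching summaries for >= 2 groups")
    if np.any(ns < 2):
        raise ParameterError("every group needs n >= 2")
    if np.any(sds < 0):
        raise ParameterError("standard deviations must be >= 0")
    big_n = int(ns.sum())
    grand = float((ns * means).sum() / big_n)
    ms_between = float((ns * (means - grand) ** 2).sum() / (k - 1))
    ms_within = float(((ns - 1) * sds ** 2).sum() / (big_n - k))
    if ms_within == 0:
        f = np.inf if ms_between > 0 else 0.0
    else:
        f = ms_between / ms_within
    p = float(stats.f.sf(f, k - 1, big_n - k))
    return float(f), p


def summary_ttest(m1, sd1, n1, m2, sd2, n2,
                  variant: str = "pooled") -> tuple[float, float]:
    """Independent two-sample t-test from summaries ('pooled' or 'welch')."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need n >= 2")
    if variant not in ("pooled", "welch"):
        raise ParameterError(f"unknown variant {variant!r}")
    t, p = stats.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                      equal_var=(variant == "pooled"))
    return float(t), float(p)


def chisq_counts(table) -> tuple[float, float]:
    """Pearson chi-square of an r x c count table (margin-based expecteds,
    no continuity correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ParameterError("need an r x c table with r, c >= 2")
    if np.any(obs < 0):
        raise ParameterError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ParameterError("zero margin in count table")
    expected = row @ col / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, float(stats.chi2.sf(chi2, df))


@dataclass(frozen=True)
class PowerSpec:
    effect_size_f: float = 0.5
    alpha: float = 0.05
    total_n: int = 86
    k_groups: int = 3

    def __post_init__(self) -> None:
        if self.effect_size_f < 0:
            raise ParameterError("effect size f must be >= 0")
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.total_n <= self.k_groups or self.k_groups < 2:
            raise ParameterError("need total_n > k_groups >= 2")


def power_oneway(spec: PowerSpec) -> float:
    """Analytic power of a fixed-effects one-way design: P(F' > F_crit) with
    F' noncentral F at lambda = f^2 * N."""
    df1 = spec.k_groups - 1
    df2 = spec.total_n - spec.k_groups
    f_crit = stats.f.isf(spec.alpha, df1, df2)
    lam = spec.effect_size_f ** 2 * spec.total_n
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


# ---------------------------------------------------------------------------
# Demographic table from a cohort table
# ---------------------------------------------------------------------------

_THREE_GROUP_VARS = ("age", "education", "head_motion")
_PATIENT_VARS = ("duration", "lesion_volume", "fma_ue", "fma_le", "mbi_c")


def demographic_table(table: CohortTable, ttest_variant: str = "pooled"
                      ) -> pd.DataFrame:
    """Recompute the demographic/clinical comparison table of a cohort:
    three-group ANOVA for shared covariates, patient-pair t-tests for
    clinical variables, chi-square for gender counts."""
    frame = table.frame
    out = []

    def summaries(col, groups):
        stats_ = []
        for g in groups:
            vals = frame.loc[frame["group"] == g, col].dropna()
            stats_.append((vals.mean(), vals.std(ddof=1), len(vals)))
        return zip(*stats_)

    for col in _THREE_GROUP_VARS:
        means, sds, ns = summaries(col, ("LSS", "RSS", "HC"))
        f, p = summary_anova(means, sds, ns)
        out.append({"variable": col, "test": "anova", "stat": f, "p": p})

    for col in _PATIENT_VARS:
        (m1, m2), (s1, s2), (n1, n2) = summaries(col, ("LSS", "RSS"))
        t, p = summary_ttest(m1, s1, n1, m2, s2, n2, variant=ttest_variant)
        out.append({"variable": col, "test": f"t_{ttest_variant}", "stat": t, "p": p})

    counts = np.array([
        [(frame["group"].eq(g) & frame["gender"].eq(sex)).sum()
         for g in ("LSS", "RSS", "HC")]
        for sex in ("male", "female")
    ])
    if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
        chi2, p = chisq_counts(counts)
    else:  # a single-gender cohort has no testable contingency
        chi2, p = np.nan, np.nan
    out.append({"variable": "gender", "test": "chisq", "stat": chi2, "p": p})
    return pd.DataFrame(out)
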