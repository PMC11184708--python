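"""Design matrices for voxelwise group models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import DesignError
from ..io_formats import GROUPS, CohortTable

DEFAULT_COVARIATES = ("age", "gender", "education", "head_motion")
PATIENT_COVARIATES = ("age", "gender", "education", "head_motion", "lesion_volume")


@dataclass
class Design:
    """An (N, p) design with an intercept, group-indicator columns and
    covariates.  Group indicators code all but the last group present."""

    matrix: np.ndarray
    columns: list[str]
    group_columns: list[int]
    groups: np.ndarray          # per-row group label
    subject_ids: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def _covariate_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    if name == "gender":
        return (frame["gender"] == "male").to_numpy(dtype=float)
    col = frame[name].to_numpy(dtype=float)
    if np.isnan(col).any():
        raise DesignError(f"covariate {name!r} has missing values")
    return col


def build_design(table: CohortTable, covariates=DEFAULT_COVARIATES) -> Design:
    """Build the group-comparison design from a cohort table.

    Raises DesignError when the result is rank-deficient.
    """
    frame = table.frame
    present = [g for g in GROUPS if (frame["group"] == g).any()]
    if len(present) < 2:
        raise DesignError("need at least two groups")
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    group_cols = []
    for g in present[:-1]:
        group_cols.append(len(names))
        cols.append((frame["group"] == g).to_numpy(dtype=float))
        names.append(f"group_{g}")
    for cov in covariates:
        cols.append(_covariate_column(frame, cov))
        names.append(cov)
    matrix = np.column_stack(cols)
    design = Design(matrix=matrix, columns=names, group_columns=group_cols,
                    groups=frame["group"].to_numpy(),
                    subject_ids=frame["id"].to_numpy())
    if design.rank < matrix.shape[1]:
        raise DesignError("design matrix is rank-deficient")
    return design


def drop_subject(design: Design, subject_id: str) -> Design:
    keep = design.subject_ids != subject_id
    if keep.all():
        raise DesignError(f"subject {subject_id!r} not in design")
    return Design(matrix=design.matrix[keep], columns=design.columns,
                  group_columns=design.group_columns,
                  groups=design.groups[keep], subject_ids=design.subject_ids[keep])
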