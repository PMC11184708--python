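"""Leave-one-patient-out reproducibility of the voxelwise group analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DesignError
from ..io_formats import BrainMask
from .design import Design, drop_subject
from .rft import cluster_mask, estimate_smoothness, grf_cluster_correct
from .voxelwise import ancova_f_map


@dataclass
class ReproducibilityMap:
    """Per-voxel count, over leave-one-out folds, of surviving-cluster
    membership."""

    counts: np.ndarray          # (dims) int
    n_folds: int
    fold_ids: list[str]


def significance_mask(subject_maps: np.ndarray, design: Design, mask: BrainMask,
                      voxel_p: float = 0.01, cluster_p: float = 0.05) -> np.ndarray:
    """Boolean volume of voxels inside GRF-surviving ANCOVA clusters."""
    stat, resid = ancova_f_map(subject_maps, design)
    smoothness = estimate_smoothness(resid, mask)
    clusters = grf_cluster_correct(stat, mask, smoothness,
                                   voxel_p=voxel_p, cluster_p=cluster_p)
    return cluster_mask(clusters, mask.grid)


def loo_reproducibility(subject_maps: np.ndarray, design: Design,
                        mask: BrainMask, voxel_p: float = 0.01,
                        cluster_p: float = 0.05) -> ReproducibilityMap:
    """One fold per patient (LSS/RSS rows of the design): rerun the full
    ANCOVA + GRF analysis without that patient and count, per voxel, the
    folds in which the voxel sits in a surviving cluster."""
    patient_ids = [sid for sid, g in zip(design.subject_ids, design.groups)
                   if g in ("LSS", "RSS")]
    if len(patient_ids) < 2:
        raise DesignError("need at least 2 patients for leave-one-out")
    counts = np.zeros(mask.grid.dims, dtype=np.int64)
    for sid in patient_ids:
        fold_design = drop_subject(design, sid)
        keep = design.subject_ids != sid
        sig = significance_mask(subject_maps[keep], fold_design, mask,
                                voxel_p=voxel_p, cluster_p=cluster_p)
        counts += sig
    return ReproducibilityMap(counts=counts, n_folds=len(patient_ids),
                              fold_ids=list(patient_ids))
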