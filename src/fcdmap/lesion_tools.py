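"""Lesion overlap maps and lesion volumes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .io_formats import VolumeGrid


@dataclass
class LesionMask:
    grid: VolumeGrid
    inside: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside).astype(bool)
        if self.inside.shape != self.grid.dims:
            raise GeometryError("lesion mask shape does not match grid dims")

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())


def overlap_map(masks: list[LesionMask]) -> np.ndarray:
    """Voxelwise count of lesion masks covering each voxel."""
    if not masks:
        raise GeometryError("need at least one lesion mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if not grid.matches(m.grid):
            raise GeometryError(f"lesion mask {m.subject_id!r} is on a different grid")
    out = np.zeros(grid.dims, dtype=np.int64)
    for m in masks:
        out += m.inside
    return out


def lesion_volume_ml(mask: LesionMask) -> float:
    """Lesion volume in millilitres: voxel count times voxel volume (mm^3) / 1000."""
    voxel_mm3 = float(np.prod(mask.grid.voxel_size))
    return mask.n_voxels * voxel_mm3 / 1000.0
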