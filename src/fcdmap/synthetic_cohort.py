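"""Synthetic three-group cohorts with known connectivity ground truth.

Each subject's voxel time series is a sum of latent band-limited network
signals (shared within spherical blobs) and voxelwise band-limited Gaussian
noise:

    y_v(t) = sum_k a_k * L_k(t) * [v in blob_k] + sigma * e_v(t)

with unit-variance latents and noise, so two voxels inside the same blob
have expected correlation a^2 / (a^2 + sigma^2).  A per-group multiplier on
a designated network's loading injects group FCD differences; clinical
scores are a linear map of each patient's true regional connectivity plus
noise.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .io_formats import BrainMask, CohortTable, Series4D, VolumeGrid
from .lesion_tools import LesionMask
from .preprocess import bandpass_array, mean_framewise_displacement, smooth_gaussian

Blob = tuple[tuple[int, int, int], float]  # (center voxel index, radius voxels)


@dataclass(frozen=True)
class NetworkSpec:
    """A set of spherical blobs sharing one latent signal with coupling
    strength ``loading``; ``group_scaled`` networks get the per-group
    multiplier applied."""

    blobs: tuple[Blob, ...]
    loading: float = 1.0
    group_scaled: bool = False

    def __post_init__(self) -> None:
        if self.loading < 0:
            raise ParameterError("loading must be >= 0")
        for _, radius in self.blobs:
            if radius < 1:
                raise ParameterError("blob radius must be >= 1 voxel")


@dataclass(frozen=True)
class ScoreModel:
    """scores = intercept + coef * (true regional connectivity) + noise."""

    intercepts: dict = field(default_factory=lambda: {"fma_ue": 20.0, "fma_le": 12.0,
                                                      "mbi_c": 40.0})
    coefficients: dict = field(default_factory=lambda: {"fma_ue": 40.0, "fma_le": 25.0,
                                                        "mbi_c": 60.0})
    noise_sd: float = 2.0


def default_networks(dims=(12, 12, 12)) -> tuple[NetworkSpec, ...]:
    nx, ny, nz = dims
    effect = NetworkSpec(blobs=(((nx // 4, ny // 2, nz // 2), 3.0),),
                         loading=1.0, group_scaled=True)
    bilateral = NetworkSpec(blobs=(((nx // 4, ny // 6, nz // 3), 2.0),
                                   ((3 * nx // 4, 5 * ny // 6, nz // 3), 2.0)),
                            loading=0.8)
    return (effect, bilateral)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (desk-scale defaults)."""

    n_per_group: tuple[int, int, int] = (25, 22, 39)  # LSS, RSS, HC
    dims: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    n_volumes: int = 220
    tr_seconds: float = 2.0
    networks: tuple[NetworkSpec, ...] = None
    smooth_fwhm_mm: float = 0.0          # spatial correlation scale of the noise
    # multiplier chosen so the induced standardized group difference of the
    # in-blob z-map feature is ~1.0 on the default desk cohort
    group_effect: tuple[float, float, float] = (1.3, 1.3, 1.0)  # LSS, RSS, HC
    noise_sd: float = 1.0
    subject_loading_sd: float = 0.12     # between-subject jitter on loadings
    score_model: ScoreModel = field(default_factory=ScoreModel)
    motion_max_mm: float = 0.4
    band: tuple[float, float] = (0.01, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group):
            raise ParameterError("group sizes must be positive")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.n_volumes < 2:
            raise ParameterError("n_volumes must be >= 2")
        if self.networks is None:
            object.__setattr__(self, "networks", default_networks(self.dims))

    @property
    def grid(self) -> VolumeGrid:
        vs = self.voxel_size_mm
        affine = np.diag([vs, vs, vs, 1.0])
        affine[:3, 3] = [-vs * (d - 1) / 2.0 for d in self.dims]
        return VolumeGrid(dims=self.dims, affine=affine)

    def full_mask(self) -> BrainMask:
        return BrainMask(grid=self.grid, inside=np.ones(self.dims, dtype=bool))


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    expected_r: dict                    # group -> expected in-blob |r| (effect net)
    effect_mask: np.ndarray             # true effect region (bool volume)
    score_model: ScoreModel
    true_features: pd.DataFrame         # per subject id: true regional connectivity


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    series: Series4D
    motion: np.ndarray
    covariates: dict
    true_feature: float                 # subject's true in-blob |r|


def subject_seed(master_seed: int, subject_id: str) -> np.random.SeedSequence:
    """Stable per-subject seed derived from (master seed, subject id)."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(subject_id.encode())])


def blob_mask(dims, center, radius) -> np.ndarray:
    center = np.asarray(center, dtype=float)
    if np.any(center < 0) or np.any(center >= np.asarray(dims)):
        raise GeometryError(f"blob center {tuple(center)} outside grid {dims}")
    grids = np.indices(dims, dtype=float)
    d2 = sum((grids[a] - center[a]) ** 2 for a in range(3))
    return d2 <= float(radius) ** 2


def _band_limited(rng, shape, tr, band) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited along the last axis."""
    x = rng.standard_normal(shape)
    x = bandpass_array(x, tr, *band)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def simulate_motion(n_volumes: int, max_mm: float = 0.4,
                    seed: int | np.random.SeedSequence = 0,
                    step_sd: float = 0.1) -> np.ndarray:
    """Reflected random-walk 6-parameter trace bounded by ``max_mm`` (same
    bound applied to rotations, in degrees)."""
    if n_volumes < 2:
        raise ParameterError("n_volumes must be >= 2")
    rng = np.random.default_rng(seed)
    steps = rng.normal(scale=step_sd * max(max_mm, 1e-12), size=(n_volumes, 6))
    steps[0] = 0.0
    walk = np.cumsum(steps, axis=0)
    if max_mm == 0:
        return np.zeros((n_volumes, 6))
    # reflect into [-max_mm, max_mm]
    period = 4.0 * max_mm
    walk = np.mod(walk + max_mm, period)
    walk = np.where(walk > 2.0 * max_mm, period - walk, walk) - max_mm
    return walk


def _effective_loadings(spec: CohortSpec, group: str, rng) -> list[float]:
    gidx = {"LSS": 0, "RSS": 1, "HC": 2}[group]
    loadings = []
    for net in spec.networks:
        a = net.loading
        if net.group_scaled:
            a *= spec.group_effect[gidx]
        a *= max(0.0, 1.0 + rng.normal(scale=spec.subject_loading_sd))
        loadings.append(a)
    return loadings


def simulate_subject(spec: CohortSpec, group: str,
                     seed: int | np.random.SeedSequence = 0
                     ) -> SimulatedSubject:
    """Simulate one subject's series, motion trace and covariates."""
    if group not in ("LSS", "RSS", "HC"):
        raise ParameterError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    dims, t = spec.dims, spec.n_volumes

    noise = rng.standard_normal((*dims, t))
    if spec.smooth_fwhm_mm > 0:
        noise = smooth_gaussian(noise, spec.smooth_fwhm_mm,
                                (spec.voxel_size_mm,) * 3)
    noise = bandpass_array(noise, spec.tr_seconds, *spec.band)
    sd = noise.std(axis=-1, keepdims=True)
    noise *= spec.noise_sd / np.where(sd > 0, sd, 1.0)

    loadings = _effective_loadings(spec, group, rng)
    data = noise
    for net, a in zip(spec.networks, loadings):
        latent = _band_limited(rng, t, spec.tr_seconds, spec.band)
        support = np.zeros(dims, dtype=bool)
        for center, radius in net.blobs:
            support |= blob_mask(dims, center, radius)
        data = data + a * support[..., None] * latent

    series = Series4D(grid=spec.grid, data=data, tr_seconds=spec.tr_seconds)
    motion = simulate_motion(t, spec.motion_max_mm, rng.integers(2 ** 31))

    is_patient = group in ("LSS", "RSS")
    covariates = {
        "age": float(np.clip(rng.normal(57.0, 9.0), 25.0, 85.0)),
        "gender": "male" if rng.random() < 0.85 else "female",
        "education": float(np.clip(rng.normal(10.0, 3.0), 0.0, 22.0)),
        "head_motion": mean_framewise_displacement(motion),
        "duration": float(np.clip(rng.normal(14.0, 10.0), 3.1, 60.0))
        if is_patient else np.nan,
    }
    a_eff = loadings[_effect_network_index(spec)]
    true_feature = a_eff ** 2 / (a_eff ** 2 + spec.noise_sd ** 2)
    return SimulatedSubject(subject_id="", group=group, series=series,
                            motion=motion, covariates=covariates,
                            true_feature=true_feature)


def _effect_network_index(spec: CohortSpec) -> int:
    for i, net in enumerate(spec.networks):
        if net.group_scaled:
            return i
    return 0


def expected_in_blob_r(spec: CohortSpec, group: str) -> float:
    """Mixing-model expectation of the in-blob pairwise |r| of the effect
    network for a subject of ``group`` with no loading jitter."""
    gidx = {"LSS": 0, "RSS": 1, "HC": 2}[group]
    net = spec.networks[_effect_network_index(spec)]
    a = net.loading * (spec.group_effect[gidx] if net.group_scaled else 1.0)
    return a ** 2 / (a ** 2 + spec.noise_sd ** 2)


def _simulate_lesion(spec: CohortSpec, group: str, rng) -> np.ndarray:
    nx, ny, nz = spec.dims
    half = nx // 2
    lo, hi = (0, half) if group == "LSS" else (half, nx)
    center = (int(rng.integers(lo + 1, max(hi - 1, lo + 2))),
              int(rng.integers(1, ny - 1)),
              int(rng.integers(1, nz - 1)))
    return blob_mask(spec.dims, center, float(rng.uniform(1.0, 1.8)))


def simulate_cohort(spec: CohortSpec):
    """Simulate a full cohort.

    Returns ``(subjects, table, ground_truth, lesions)`` where ``lesions``
    maps patient id -> LesionMask.
    """
    from .lesion_tools import lesion_volume_ml

    subjects: list[SimulatedSubject] = []
    rows = []
    lesions: dict[str, LesionMask] = {}
    truths = []

    labels = (["LSS"] * spec.n_per_group[0] + ["RSS"] * spec.n_per_group[1]
              + ["HC"] * spec.n_per_group[2])
    counters = {"LSS": 0, "RSS": 0, "HC": 0}
    for group in labels:
        counters[group] += 1
        sid = f"{group}{counters[group]:03d}"
        ss = subject_seed(spec.seed, sid)
        subj = simulate_subject(spec, group, ss)
        subj.subject_id = sid
        subjects.append(subj)

        row = {"id": sid, "group": group, **subj.covariates}
        if group in ("LSS", "RSS"):
            rng = np.random.default_rng(ss.spawn(1)[0])
            lesion = LesionMask(grid=spec.grid,
                                inside=_simulate_lesion(spec, group, rng),
                                subject_id=sid)
            lesions[sid] = lesion
            row["lesion_volume"] = lesion_volume_ml(lesion)
            sm = spec.score_model
            for score in ("fma_ue", "fma_le", "mbi_c"):
                val = (sm.intercepts[score]
                       + sm.coefficients[score] * subj.true_feature
                       + (rng.normal(scale=sm.noise_sd) if sm.noise_sd > 0 else 0.0))
                lo, hi = {"fma_ue": (0, 66), "fma_le": (0, 34), "mbi_c": (0, 100)}[score]
                row[score] = float(np.clip(val, lo, hi))
        rows.append(row)
        truths.append({"id": sid, "group": group, "true_feature": subj.true_feature})

    table = CohortTable(pd.DataFrame(rows))
    net = spec.networks[_effect_network_index(spec)]
    effect_mask = np.zeros(spec.dims, dtype=bool)
    for center, radius in net.blobs:
        effect_mask |= blob_mask(spec.dims, center, radius)
    truth = GroundTruth(
        expected_r={g: expected_in_blob_r(spec, g) for g in ("LSS", "RSS", "HC")},
        effect_mask=effect_mask,
        score_model=spec.score_model,
        true_features=pd.DataFrame(truths),
    )
    return subjects, table, truth, lesions


def null_spec(spec: CohortSpec | None = None, **overrides) -> CohortSpec:
    """A copy of ``spec`` with every group effect removed (pure-noise networks
    retained at HC loading) — used for false-positive calibration."""
    base = spec if spec is not None else CohortSpec()
    return replace(base, group_effect=(1.0, 1.0, 1.0), **overrides)
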