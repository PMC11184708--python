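"""End-to-end orchestration: simulate -> preprocess -> FCD -> inference.

``run_pipeline`` drives everything from a single RunConfig (loadable from a
YAML file) and writes all products plus a JSON manifest; the intermediate
helpers (``cohort_fcd_maps``, ``analyze_cohort``) are reusable directly and
are what the test-suite and acceptance script call.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ParameterError
from .fcd_core import DistanceConfig, compute_fcd
from .group_inference import (DEFAULT_COVARIATES, PATIENT_COVARIATES,
                              adjust_family, ancova_f_map, build_design,
                              clinical_regression, estimate_smoothness,
                              extract_cluster_feature, grf_cluster_correct,
                              posthoc_pairwise)
from .io_formats import (BrainMask, CohortTable, write_cohort, write_mask,
                         write_motion, write_series, write_volume)
from .preprocess import (NuisanceModel, exceeds_motion_limit, preprocess_series)
from .synthetic_cohort import CohortSpec, simulate_cohort


@dataclass
class PreprocessConfig:
    drop: int = 10
    fwhm_mm: float = 6.0
    band: tuple[float, float] = (0.01, 0.1)
    trans_limit_mm: float = 2.5
    rot_limit_deg: float = 2.5
    smooth_before_filter: bool = True


@dataclass
class InferenceConfig:
    voxel_p: float = 0.01
    cluster_p: float = 0.05
    fdr_alpha: float = 0.05
    covariates: tuple = DEFAULT_COVARIATES
    patient_covariates: tuple = PATIENT_COVARIATES

    def __post_init__(self) -> None:
        for p in (self.voxel_p, self.cluster_p, self.fdr_alpha):
            if not (0 < p < 1):
                raise ParameterError(f"threshold {p} outside (0, 1)")


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcd: DistanceConfig = field(default_factory=DistanceConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    out_dir: str = "fcdmap_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            for key in ("n_per_group", "dims", "group_effect", "band"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = CohortSpec(**c)
        if "preprocess" in raw:
            p = dict(raw["preprocess"])
            if "band" in p:
                p["band"] = tuple(p["band"])
            kwargs["preprocess"] = PreprocessConfig(**p)
        if "fcd" in raw:
            kwargs["fcd"] = DistanceConfig(**raw["fcd"])
        if "inference" in raw:
            i = dict(raw["inference"])
            for key in ("covariates", "patient_covariates"):
                if key in i:
                    i[key] = tuple(i[key])
            kwargs["inference"] = InferenceConfig(**i)
        if "out_dir" in raw:
            kwargs["out_dir"] = raw["out_dir"]
        return cls(**kwargs)


def preprocess_subject(subject, mask: BrainMask, cfg: PreprocessConfig):
    """Apply the preprocessing chain to one simulated subject."""
    return preprocess_series(
        subject.series, trace=subject.motion, model=NuisanceModel(),
        drop=cfg.drop, fwhm_mm=cfg.fwhm_mm, band=cfg.band, mask=mask,
        smooth_before_filter=cfg.smooth_before_filter)


def cohort_fcd_maps(spec: CohortSpec,
                    pre_cfg: PreprocessConfig | None = None,
                    dist_cfg: DistanceConfig | None = None,
                    drop: int | None = None):
    """Simulate a cohort and compute per-subject FCD z-maps.

    Returns ``(maps, table, truth, lesions, mask)`` where ``maps`` is a dict
    of (N, V) arrays keyed by 'g_z'/'s_z'/'l_z' (canonical in-mask order) and
    motion-excluded subjects are removed from both maps and table.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    if drop is not None:
        pre_cfg = PreprocessConfig(**{**asdict(pre_cfg), "drop": drop})
    dist_cfg = dist_cfg or DistanceConfig()
    subjects, table, truth, lesions = simulate_cohort(spec)
    mask = spec.full_mask()
    inside = mask.inside

    keep_rows = []
    stacked: dict[str, list[np.ndarray]] = {"g_z": [], "s_z": [], "l_z": []}
    for i, subj in enumerate(subjects):
        if exceeds_motion_limit(subj.motion, pre_cfg.trans_limit_mm,
                                pre_cfg.rot_limit_deg):
            continue
        pre = preprocess_subject(subj, mask, pre_cfg)
        maps = compute_fcd(pre, mask, dist_cfg)
        from .io_formats import mask_indices
        idx = mask_indices(mask)
        for key, vol in (("g_z", maps.g_z), ("s_z", maps.s_z), ("l_z", maps.l_z)):
            stacked[key].append(vol[idx[:, 0], idx[:, 1], idx[:, 2]])
        keep_rows.append(i)

    table = CohortTable(table.frame.iloc[keep_rows].reset_index(drop=True))
    arrays = {k: np.vstack(v) for k, v in stacked.items()}
    return arrays, table, truth, lesions, mask


def analyze_cohort(maps: np.ndarray, table: CohortTable, mask: BrainMask,
                   inf_cfg: InferenceConfig | None = None):
    """ANCOVA + smoothness + GRF cluster correction for one FCD measure.

    Returns ``(stat_map, clusters, smoothness, design)``.
    """
    inf_cfg = inf_cfg or InferenceConfig()
    design = build_design(table, covariates=inf_cfg.covariates)
    stat, resid = ancova_f_map(maps, design)
    smoothness = estimate_smoothness(resid, mask)
    clusters = grf_cluster_correct(stat, mask, smoothness,
                                   voxel_p=inf_cfg.voxel_p,
                                   cluster_p=inf_cfg.cluster_p)
    return stat, clusters, smoothness, design


def regression_family(maps: dict[str, np.ndarray], cluster_specs,
                      table: CohortTable, mask: BrainMask,
                      inf_cfg: InferenceConfig | None = None):
    """Regress each (cluster feature, clinical score) pair over all patients
    and BH-adjust the family of p-values.

    ``cluster_specs`` is a list of (label, map_key, Cluster).
    """
    from .io_formats import mask_indices

    inf_cfg = inf_cfg or InferenceConfig()
    patients = table.patients()
    keep = table.frame["group"].isin(["LSS", "RSS"]).to_numpy()
    idx = mask_indices(mask)
    cov_cols = [c for c in inf_cfg.patient_covariates]
    cov = patients.frame[[c for c in cov_cols if c != "gender"]].astype(float)
    if "gender" in cov_cols:
        cov = cov.assign(gender=(patients.frame["gender"] == "male").astype(float))

    rows = []
    for label, key, cluster in cluster_specs:
        vec = maps[key][keep]
        feats = []
        for subject_maps in vec:
            vol = np.zeros(mask.grid.dims)
            vol[idx[:, 0], idx[:, 1], idx[:, 2]] = subject_maps
            feats.append(extract_cluster_feature(vol, cluster))
        feats = np.asarray(feats)
        for score in ("fma_ue", "fma_le", "mbi_c"):
            rows.append(clinical_regression(
                feats, patients.frame[score].to_numpy(dtype=float), cov,
                feature_label=f"{label}_{key}", score_label=score))
    return adjust_family(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write products plus a manifest under
    ``config.out_dir``.  Identical config (including the seed) yields
    identical product checksums."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    manifest: dict = {"version": __version__, "seed": config.cohort.seed,
                      "stages": {}, "products": {}}
    try:
        subjects, table, truth, lesions = simulate_cohort(config.cohort)
        mask = config.cohort.full_mask()
        sim_dir = out / "simulated"
        sim_dir.mkdir(exist_ok=True)
        write_cohort(table, sim_dir / "participants.tsv")
        write_mask(mask, sim_dir / "mask.nii")
        for subj in subjects:
            write_series(subj.series, sim_dir / f"{subj.subject_id}_bold.nii")
            write_motion(subj.motion, sim_dir / f"{subj.subject_id}_motion.txt")
        import nibabel as nib
        for sid, lesion in lesions.items():
            # write directly: a lesion may legitimately be a single voxel
            nib.save(nib.Nifti1Image(lesion.inside.astype(np.uint8),
                                     lesion.grid.affine),
                     str(sim_dir / f"{sid}_lesion.nii"))
        manifest["stages"]["simulate"] = {"n_subjects": len(subjects)}

        stage = "preprocess+fcd"
        from .io_formats import mask_indices
        idx = mask_indices(mask)
        fcd_dir = out / "fcd"
        fcd_dir.mkdir(exist_ok=True)
        stacked: dict[str, list] = {"g_z": [], "s_z": [], "l_z": []}
        keep_rows = []
        excluded = []
        for i, subj in enumerate(subjects):
            if exceeds_motion_limit(subj.motion, config.preprocess.trans_limit_mm,
                                    config.preprocess.rot_limit_deg):
                excluded.append(subj.subject_id)
                continue
            pre = preprocess_subject(subj, mask, config.preprocess)
            maps = compute_fcd(pre, mask, config.fcd)
            for key, vol in maps.as_dict().items():
                write_volume(vol, mask.grid,
                             fcd_dir / f"{subj.subject_id}_{key}.nii")
            sidecar = {"criterion_mm": config.fcd.criterion_mm,
                       "epsilon": config.fcd.epsilon,
                       "mask_sha256": hashlib.sha256(
                           mask.inside.tobytes()).hexdigest()}
            (fcd_dir / f"{subj.subject_id}_fcd.json").write_text(
                json.dumps(sidecar, indent=2))
            for key in stacked:
                vol = maps.as_dict()[key]
                stacked[key].append(vol[idx[:, 0], idx[:, 1], idx[:, 2]])
            keep_rows.append(i)
        table = CohortTable(table.frame.iloc[keep_rows].reset_index(drop=True))
        arrays = {k: np.vstack(v) for k, v in stacked.items()}
        manifest["stages"]["preprocess+fcd"] = {
            "n_analyzed": len(keep_rows), "motion_excluded": excluded}

        stage = "inference"
        inf_dir = out / "inference"
        inf_dir.mkdir(exist_ok=True)
        cluster_specs = []
        for key in ("g_z", "s_z", "l_z"):
            stat, clusters, smoothness, design = analyze_cohort(
                arrays[key], table, mask, config.inference)
            report = [{"measure": key, "size": c.size,
                       "peak_stat": round(c.peak_stat, 4),
                       "peak_mm": [round(x, 1) for x in c.peak_mm],
                       "p_fwe": round(c.p_fwe, 6)} for c in clusters]
            lines = ["measure\tsize\tpeak_x\tpeak_y\tpeak_z\tpeak_stat\tp_fwe"]
            for r in report:
                lines.append("\t".join(str(x) for x in (
                    r["measure"], r["size"], *r["peak_mm"],
                    r["peak_stat"], r["p_fwe"])))
            (inf_dir / f"clusters_{key}.tsv").write_text("\n".join(lines) + "\n")
            for ci, c in enumerate(clusters):
                cluster_specs.append((f"cluster{ci}", key, c))
            manifest["stages"].setdefault("inference", {})[key] = {
                "n_clusters": len(clusters),
                "fwhm_mm": [round(f, 3) for f in smoothness.fwhm_mm]}

        stage = "regression"
        if cluster_specs and len(table.patients()) >= 10:
            rows = regression_family(arrays, cluster_specs, table, mask,
                                     config.inference)
            lines = ["feature\tscore\tbeta\tr_squared\tt\tp\tp_adjusted"]
            for r in rows:
                lines.append(f"{r.feature_label}\t{r.score_label}\t{r.beta:.6g}"
                             f"\t{r.r_squared:.4f}\t{r.t:.4f}\t{r.p:.6g}"
                             f"\t{r.p_adjusted:.6g}")
            (inf_dir / "regression.tsv").write_text("\n".join(lines) + "\n")
            manifest["stages"]["regression"] = {"n_rows": len(rows)}

        for path in sorted(out.rglob("*")):
            if path.is_file() and path.name != "manifest.json":
                manifest["products"][str(path.relative_to(out))] = _sha256(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
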