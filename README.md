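# fcdmap

Distance-dependent functional connectivity density (FCD) mapping for
resting-state fMRI, from 4D volumes to voxelwise group inference:

- **FCD engine** — per-voxel mean absolute Pearson correlation with all other
  in-mask voxels (weighted variant, no correlation threshold), partitioned
  into short- and long-range maps by a Euclidean distance criterion
  (12 mm default; 6/18 mm variants), Fisher r-to-z transformed.
- **Preprocessing** — volume dropping, motion-exclusion screening
  (2.5 mm / 2.5°), Power-style framewise displacement, nuisance regression
  (linear trend, tissue means, Friston-24 motion expansion), 6 mm FWHM
  Gaussian smoothing with masked renormalization, 0.01–0.1 Hz band-pass.
- **Group inference** — voxelwise ANCOVA (group effect adjusted for
  covariates), residual-based smoothness estimation, Gaussian-random-field
  cluster-level FWE correction (voxel p < 0.01, cluster p < 0.05,
  26-connectivity), covariate-adjusted post-hoc t / Cohen's d maps,
  clinical-score regression with Benjamini–Hochberg FDR, leave-one-patient-out
  reproducibility maps, seed-based FC, summary-statistic demographic tests
  and noncentral-F design power.
- **Synthetic cohorts** — a three-group generator (default 25/22/39) with
  band-limited latent network signals, a known mixing model
  (in-blob r = a²/(a² + σ²)), injected group effects of standardized
  magnitude ≈ 1, lateralized lesion masks, and clinical scores linearly
  coupled to true regional connectivity — so the whole pipeline is testable
  without any data download.
- **Lesion tools** — overlap maps and lesion volumes.

## CLI

```sh
fcdmap simulate --config examples/desk_cohort.yaml --seed 1 --out scratch/sim
fcdmap preprocess scratch/sim/LSS001_bold.nii \
    --motion scratch/sim/LSS001_motion.txt --mask scratch/sim/mask.nii \
    --drop 10 --fwhm 6 --band 0.01,0.1 --out scratch/LSS001_pre.nii
fcdmap fcd scratch/LSS001_pre.nii --mask scratch/sim/mask.nii \
    --criterion 12 --out-prefix scratch/LSS001
fcdmap lesion-overlap scratch/sim/LSS*_lesion.nii --out scratch/overlap.nii
fcdmap table1 scratch/sim/participants.tsv
fcdmap power --f 0.5 --alpha 0.05 --n 86 --groups 3
fcdmap run --config examples/desk_cohort.yaml --seed 1 --out scratch/run
```

`fcdmap run` chains simulate → preprocess → FCD → ANCOVA/GRF → regression
and writes a `manifest.json` with a parameter echo and SHA-256 checksums of
every product; identical config + seed reproduces identical checksums.
Exit codes: 2 configuration, 3 data, 4 numerical errors.

## File formats

NIfTI-1 for volumes and masks; tab-separated participants table
(`id, group ∈ {LSS,RSS,HC}, age, gender, education, head_motion,
lesion_volume, duration, fma_ue, fma_le, mbi_c`, patient-only columns blank
for controls); plain-text 6-column motion traces (3 translations mm,
3 rotations degrees, one row per volume).

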