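# Desk-scale cohort: protocol defaults on a 12x12x12 grid at 3 mm.
cohort:
  n_per_group: [25, 22, 39]     # LSS, RSS, HC
  dims: [12, 12, 12]
  voxel_size_mm: 3.0
  n_volumes: 230
  tr_seconds: 2.0
  noise_sd: 1.0
  group_effect: [1.3, 1.3, 1.0]
  seed: 0

preprocess:
  drop: 10
  fwhm_mm: 6.0
  band: [0.01, 0.1]
  trans_limit_mm: 2.5
  rot_limit_deg: 2.5

fcd:
  criterion_mm: 12.0            # 6 and 18 for the validation variants

inference:
  voxel_p: 0.01
  cluster_p: 0.05
  fdr_alpha: 0.05
  covariates: [age, gender, education, head_motion]
  patient_covariates: [age, gender, education, head_motion, lesion_volume]

out_dir: scratch/desk_run
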