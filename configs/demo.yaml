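# Demo study: 2 sexes x 2 exposure groups x 6 brain regions x 5 timepoints.
# All keys are schema-validated; unknown keys are rejected.
seed: 11
out_dir: scratch/demo_run

fields:
  n_fields_per_region: 1
  width_px: 256
  height_px: 256
  n_nuclei: 40
  nucleus_radius_px: 8.0
  noise_sd: 0.18          # contrast/noise = 5 with fg 1.0, bg 0.1
  glial_marker: IBA1
  phenotype_marker: iNOS

segmentation:
  radius_fraction: 0.05   # Phansalkar window radius, fraction of image width
  smooth_sigma: 1.0

phenotyping:
  phenotype_overlap_threshold: 0.25

pet:
  shape: [64, 64, 48]
  noise_sd: 5.0

cohort:
  sexes: [M, F]
  outcomes: [iba1_density, inos_iba1_density, gfap_density, c3_gfap_intensity]
  n_animals_per_group: 6
  true_gmr: 2.0
  sd_log_animal: 0.3

stats:
  alpha: 0.05
  use_t: true
  collapse: by_cell
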