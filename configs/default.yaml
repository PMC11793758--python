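# Full-pipeline experiment: 8 synthetic specimens, wet month then dry
# month on the same specimen (the dry baseline is the wet endpoint).
# All lengths in mm.  Every random stage derives from `seed`.
seed: 101
specimens: 8
noise_sigma_mm: 0.0279      # scanner noise SD applied along vertex normals

cutoff:
  mode: fixed               # or: accuracy_report (+ report_path)
  value_mm: 0.040

arch:
  span_mm: 50.0
  depth_mm: 40.0
  band_width_mm: 8.0
  occlusal_height_mm: 3.0
  resolution_mm: 0.8        # target edge length

wet_scenario:               # mild deformation during wet storage
  posterior_shrink_mm: 0.05
  palatal_lift_mm: 0.07
  buccal_retraction_mm: 0.06
  smoothness_mm: 10.0

dry_scenario:               # stronger deformation during dry storage
  posterior_shrink_mm: 0.09
  palatal_lift_mm: 0.12
  buccal_retraction_mm: 0.11
  smoothness_mm: 10.0

magnitude_jitter: 0.2       # +-20% per-specimen scatter of magnitudes

icp:
  max_iter: 200
  rms_tol: 1.0e-6
  sample_size: 50000

output_dir: archmorph_out
write_meshes: true
write_colormaps: false
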