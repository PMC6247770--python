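# Multiphase quantification settings.
kinetic:
  lambda: 0.9
  t1_tissue_s: 1.9
  t1_blood_s: 2.1
  alpha: 0.785
  tau_s: 0.9
  pld_s: 0.4
  delta_t_s: 0.2
pipeline:
  n_supervoxels: 60
  compactness: 0.1
  # smooth_fwhm_mm: 0.625   # default: 2 in-plane voxels
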