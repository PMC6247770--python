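# Labelling-efficiency simulation at the optimised operating point.
# Add a `grid:` block to sweep thickness / velocity / B1 / phase.
pulse_train:
  duration_us: 600.0
  interval_us: 1200.0
  peak_b1_ut: 10.0        # 5 uT quoted amplitude, pulse-mean convention
  phase_increment_deg: 0.0
geometry:
  thickness_mm: 2.0
  g_mean_ratio: 0.05
spin:
  velocity_mm_s: 124.0
  t1_s: 2.1
  t2_s: 0.033
# grid:
#   thicknesses_mm: [1.0, 2.0, 4.0]
#   velocities_mm_s: [100.0, 124.0, 200.0]
#   b1_amps_ut: [1.0, 5.0, 10.0]
#   b1_convention: peak
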