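# Synthetic mouse-brain multiphase ASL dataset.
phantom:
  shape: [64, 64, 8]
  phase_amplitude_deg: 60.0
  tumour: false
acquisition:
  pld_s: 0.4
  tau_s: 0.9
  target_snr: 15.1
  triggered: true
  noise: gaussian
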