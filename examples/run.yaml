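# Desk-scale full study: 13 subjects x 2 conditions, 62 channels at 250 Hz.
# Runs the whole pipeline in roughly a quarter of an hour on one CPU.
seed: 7
generator:
  n_subjects: 13
  montage_name: std62
  native_rate: 250
  n_targets: 60
  n_deviants: 60
  n_standards: 720
  target_parietal_amp: 8.0
preprocessing:
  amp_uv: 100
  grad_uv: 75
erp:
  electrodes: [CPz, Pz, POz]
  windows: [early, late]
classification:
  pairs: [t/st, d/st, t/d]
  channels: [all62, parietal6, parietal2]
  windows: [early, late]
  n_repetitions: 2
  n_folds: 10
  transfer: both
log_level: INFO
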