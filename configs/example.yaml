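# Reproducible end-to-end run: 26 synthetic participants per empathy group,
# fitted with all three candidate empathy-update models.
seed: 11
n_per_group: 26
generating_model: M3_signsplit_halfsplit
fitting:
  models: [M1_single, M2_signsplit, M3_signsplit_halfsplit]
  n_restarts: 10
  rw_trials: all
  half_boundary: 24
n_bms_samples: 100000
output_dir: runs/example
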