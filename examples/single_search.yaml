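# One traversal on the reference field: start in the left-torso
# background, study-default hyperparameters.
field: reference
region: left_torso
search:
  start: [560, 470]
  step_size_interval: 2
  rolling_window_length: 10
  max_steps: 100
  quality_threshold: 0.95
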