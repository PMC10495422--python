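# Rolling-window-length sweep on the left torso at the default step
# size interval; pair with --seed to vary the start sample.
field: reference
regions:
  left_torso: [[540, 80], [980, 80], [980, 1000], [540, 1000]]
n_starts: 500
start_sampling_seed: 7
step_size_intervals: [2]
rolling_window_lengths: [2, 5, 10, 15, 20]
max_steps: 100
quality_threshold: 0.95
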