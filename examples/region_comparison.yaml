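# Region-comparison study at the study defaults: five torso regions,
# 1000 random starts each, step size interval 2, rolling window 10,
# 100-step cap. Produces a five-row summary table whose lower-left row
# is structurally forced to zero success at the full 100-step length.
field: reference
regions: reference
n_starts: 1000
start_sampling_seed: 7
step_size_intervals: [2]
rolling_window_lengths: [10]
max_steps: 100
quality_threshold: 0.95
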