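# echonav

Finding an echo window — a spot on the chest where the heart can be imaged
without obstruction by ribs or lungs — is the first and hardest step of a
transthoracic echocardiography (TTE) exam, and the main obstacle to
automating it with a probe-carrying robot arm. `echonav` implements a
feedback-driven search for the optimal probe position on a 2D torso grid:
an adaptive-step local search with a short-term "rolling window" memory
that navigates using only an image-quality score at each position. The
package bundles a synthetic quality-field simulator that stands in for the
CNN image-scoring stack, and a Monte-Carlo harness for characterising the
search (success rate, traversal length, final image quality) across search
regions and hyperparameters. It is aimed at researchers prototyping
robotic ultrasound acquisition protocols who need a reproducible, purely
computational testbed for the navigation layer.

## The algorithm

Positions are integer pixel coordinates $(x, y)$ on the body-camera frame
(origin top-left, $y$ downward). The probe may move only inside an
operator-calibrated 4-vertex polygon, the *search region*. A quality
oracle assigns every position a signed score $q \in [-1, 1]$: the sign is
the good/bad image classification and $|q|$ the classifier's probability,
so $q = +0.986$ is a confidently good image and $q = -0.998$ a confidently
bad one.

Starting from a chosen position with step size $s = 1$, each iteration:

1. scores the current position; if $q \ge \tau$ (threshold, default 0.95)
   the traversal ends in success;
2. scores the *step group* — the in-region positions $s$ pixels to the
   north, south, east and west — and selects the best candidate
   (ties: N, S, E, W priority);
3. checks the candidate against the rolling window, a FIFO of the last
   $L$ selected (position, quality) pairs: has this exact position been
   visited before (*revisit*), and would appending its quality lower the
   window's mean (*mean decrease*)?
4. updates the step size: $s \leftarrow s + \Delta$ if either check fires
   (a penalty — jump further to escape), else
   $s \leftarrow \max(1, s - \Delta)$ (progress — focus locally), where
   $\Delta$ is the user-set *step size interval*;
5. pushes the candidate into the window and moves there.

The run fails after `max_steps` moves (default 100) without meeting the
threshold. Terminal positions are never recorded in the window, so its
contents can all be read as past mistakes. In the limit
$\Delta = 0, L = 0$ the loop reduces exactly to plain steepest-ascent
4-neighbour hill climbing.

The synthetic oracle models the apical window as a thin slanted Gaussian
ridge: $q(x,y) = \mathrm{clip}\big(b + (p - b)\,
e^{-d^2 / 2\sigma^2} + \varepsilon,\ -1, 1\big)$, with $d$ the distance to
the band segment, peak $p$, background $b$, ridge half-width $\sigma$ and
seeded pixel noise $\varepsilon$. Positions on the band also carry an
apical view label (A4Ch on the first stretch of the band, A2Ch on the
rest), mirroring a view classifier.

## Worked example

One traversal from a background start on the bundled reference field:

```sh
$ echonav search --config examples/single_search.yaml --out out/search
success after 50 steps, final quality 0.999, window A4CH
```

The search started at (560, 470), well off the band, wandered with
growing steps while penalised, and reached an above-threshold position on
the ridge after 50 moves; the final image is classified as an apical
four-chamber view. `out/search/traversal_log.tsv` holds the per-iteration
positions, qualities, step sizes and penalty flags.

The five-region comparison study (1000 random starts per region, step
size interval 2, rolling window length 10, 100-step cap):

```sh
$ echonav experiment --config examples/region_comparison.yaml --out out/exp
     region  step_size_interval  rolling_window_length  n_starts  success_rate  mean_last_quality  mean_traversal_length  mean_evaluations
 left_torso                   2                     10      1000         0.341          -0.234349                 85.888           421.664
 lower_left                   2                     10      1000         0.000          -0.926300                100.000           481.493
middle_left                   2                     10      1000         0.852           0.719933                 60.219           294.665
 upper_left                   2                     10      1000         0.264          -0.367228                 91.202           444.782
whole_torso                   2                     10      1000         0.172          -0.573439                 93.244           460.728
```

Reading the table: the middle-left torso — where the apical window sits —
is by far the best calibration choice (85% success, shortest traversals,
highest final quality); the lower-left torso contains no echo window at
all, so every one of its 1000 traversals fails after exactly 100 steps
with near-background final quality. `runs.tsv` holds one record per
traversal (start, endpoint, success, view label) for start-point and
endpoint maps (`--maps` renders them), and `manifest.json` lets the exact
run be reproduced with `--config manifest.json`.

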