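"""Shared fixtures: the reference landscape and small synthetic helpers."""

from __future__ import annotations

import numpy as np
import pytest

from echonav import (
    FieldOracle,
    GridPosition,
    QualityField,
    SearchRegion,
    SyntheticFieldSpec,
    generate_field,
    reference_field_spec,
    reference_regions,
)


@pytest.fixture(scope="session")
def ref_spec() -> SyntheticFieldSpec:
    return reference_field_spec()


@pytest.fixture(scope="session")
def ref_field(ref_spec):
    return generate_field(ref_spec)


@pytest.fixture(scope="session")
def ref_oracle(ref_field):
    return FieldOracle(ref_field)


@pytest.fixture(scope="session")
def ref_regions(ref_spec):
    return reference_regions(ref_spec.canvas_width, ref_spec.canvas_height)


@pytest.fixture(scope="session")
def trend_study(ref_spec, ref_oracle, ref_regions):
    """One-at-a-time sweeps of the two hyperparameters on the left-torso
    region, 500 starts per setting, three start-sampling seeds. Returns
    (interval_points, window_points) as lists of (setting, success_rate)
    pairs, one per setting and seed."""
    from echonav import ExperimentConfig, run_experiment

    region = {"left_torso": ref_regions["left_torso"]}
    interval_pts, window_pts = [], []
    for seed in (7, 8, 9):
        s = run_experiment(
            ExperimentConfig(
                field_spec=ref_spec, regions=region, n_starts=500, start_sampling_seed=seed,
                step_size_intervals=(1, 2, 3, 4, 5, 6), rolling_window_lengths=(10,), max_steps=100,
            ),
            ref_oracle,
        ).summary
        interval_pts += list(zip(s["step_size_interval"], s["success_rate"]))
        s2 = run_experiment(
            ExperimentConfig(
                field_spec=ref_spec, regions=region, n_starts=500, start_sampling_seed=seed,
                step_size_intervals=(2,), rolling_window_lengths=(2, 5, 10, 15, 20), max_steps=100,
            ),
            ref_oracle,
        ).summary
        window_pts += list(zip(s2["rolling_window_length"], s2["success_rate"]))
    return interval_pts, window_pts


@pytest.fixture
def big_square() -> SearchRegion:
    return SearchRegion.from_vertex_list([(0, 0), (199, 0), (199, 199), (0, 199)], 200, 200)


def make_smooth_field(rng: np.random.Generator, width: int = 40, height: int = 40) -> QualityField:
    """A random smooth noise-free landscape: a few Gaussian bumps over a
    low-quality background, peak pushed above 0.95 so searches can succeed."""
    ys, xs = np.mgrid[0:height, 0:width]
    q = np.full((height, width), -0.9)
    n_bumps = rng.integers(1, 4)
    for _ in range(n_bumps):
        cx = rng.uniform(5, width - 5)
        cy = rng.uniform(5, height - 5)
        sigma = rng.uniform(3, 8)
        amp = rng.uniform(0.8, 1.88)
        q = q + amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma**2))
    q = np.clip(q, -1.0, 1.0)
    return QualityField(quality=q, labels=np.zeros_like(q, dtype=np.int8))


def random_quad_region(rng: np.random.Generator, width: int, height: int) -> SearchRegion:
    """A random simple (convex) quadrilateral on the canvas, built by
    sorting four random points by angle around their centroid."""
    while True:
        pts = np.column_stack(
            [rng.integers(0, width, size=4), rng.integers(0, height, size=4)]
        ).astype(float)
        cx, cy = pts.mean(axis=0)
        order = np.argsort(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx))
        pts = pts[order].astype(int)
        if len({tuple(p) for p in pts}) < 4:
            continue
        try:
            return SearchRegion.from_vertex_list([tuple(p) for p in pts], width, height)
        except Exception:
            continue


def steepest_ascent_path(
    quality: np.ndarray,
    region: SearchRegion,
    start: GridPosition,
    max_steps: int,
    threshold: float,
) -> list[GridPosition]:
    """Independent plain steepest-ascent 4-neighbour hill climber.

    Moves unconditionally to the best in-region neighbour (N, S, E, W
    priority on ties) until the threshold is met or the step cap is hit.
    Written directly against the quality array, sharing no code with the
    search module.
    """
    pos = GridPosition(*start)
    path = [pos]
    for _ in range(max_steps):
        if quality[pos.y, pos.x] >= threshold:
            break
        best = None
        best_q = None
        for dx, dy in ((0, -1), (0, 1), (1, 0), (-1, 0)):
            cand = GridPosition(pos.x + dx, pos.y + dy)
            if not region.contains(cand):
                continue
            q = quality[cand.y, cand.x]
            if best_q is None or q > best_q:
                best, best_q = cand, q
        if best is None:
            break
        pos = best
        path.append(pos)
    return path
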