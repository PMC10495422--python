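"""Monte-Carlo harness: region comparison, hyperparameter sweeps, maps, trends.

Reproduces the control-module study design: draw random start points
uniformly inside a search region, run the window search from each under a
grid of (step size interval, rolling window length) settings, and
aggregate success rate, mean quality of the last image and mean traversal
length per region and parameter combination, keeping per-run records for
start-point and endpoint maps. Second-order polynomial trendlines
summarise how the aggregates move with each hyperparameter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import GridPosition, SearchRegion, InvalidRegionError
from .oracle import QualityOracle, SyntheticFieldSpec, reference_field_spec
from .search import SearchConfig, run_search

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "TrendFit",
    "sample_starts",
    "run_experiment",
    "fit_trend",
    "reference_regions",
    "REFERENCE_REGION_NAMES",
]

# ---------------------------------------------------------------------------
# region fixtures
# ---------------------------------------------------------------------------

REFERENCE_REGION_NAMES = ("whole_torso", "left_torso", "upper_left", "lower_left", "middle_left")

# Fractions of the 1080x1080 reference canvas. Anatomical left is toward
# increasing x (camera facing down on a supine patient). The lower-left
# fixture is deliberately disjoint from the apical band so it contains no
# above-threshold position.
_REFERENCE_REGION_VERTICES = {
    "whole_torso": ((100, 80), (980, 80), (980, 1000), (100, 1000)),
    "left_torso": ((540, 80), (980, 80), (980, 1000), (540, 1000)),
    "upper_left": ((540, 80), (980, 80), (980, 540), (540, 540)),
    "lower_left": ((540, 660), (980, 660), (980, 1000), (540, 1000)),
    "middle_left": ((540, 400), (980, 400), (980, 700), (540, 700)),
}


def reference_regions(canvas_width: int = 1080, canvas_height: int = 1080) -> dict[str, SearchRegion]:
    """The five named torso-region fixtures of the region-comparison study."""
    return {
        name: SearchRegion.from_vertex_list(verts, canvas_width, canvas_height)
        for name, verts in _REFERENCE_REGION_VERTICES.items()
    }


# ---------------------------------------------------------------------------
# start-point sampling
# ---------------------------------------------------------------------------


def sample_starts(region: SearchRegion, n: int, seed: int) -> list[GridPosition]:
    """Draw ``n`` start points uniformly over the integer pixels inside the
    region polygon (boundary included), reproducibly from ``seed``.

    Uses rejection sampling from the polygon's bounding box; a region
    containing no integer pixel is invalid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    minx, miny, maxx, maxy = region.bounds()
    rng = np.random.default_rng(seed)
    out: list[GridPosition] = []
    # Rejection sampling in batches; acceptance rate is area / bbox area,
    # bounded below by 1/2 for any simple quadrilateral with bbox-tight
    # vertices, so this converges fast.
    attempts = 0
    while len(out) < n:
        batch = max(64, 2 * (n - len(out)))
        xs = rng.integers(minx, maxx + 1, size=batch)
        ys = rng.integers(miny, maxy + 1, size=batch)
        inside = region.contains_many(xs, ys)
        for x, y, ok in zip(xs, ys, inside):
            if ok:
                out.append(GridPosition(int(x), int(y)))
                if len(out) == n:
                    break
        attempts += 1
        if attempts > 1000 and not out:
            raise InvalidRegionError("region contains no integer pixel")
    return out


# ---------------------------------------------------------------------------
# experiment configuration and execution
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """A full Monte-Carlo study: field, regions, sweep grids, seeds.

    The parameter grid is the Cartesian product of
    ``step_size_intervals`` x ``rolling_window_lengths``; every region is
    run under every combination with the same ``n_starts`` sampled start
    points (per-region streams are derived from ``start_sampling_seed``
    so regions are reproducible independently).
    """

    field_spec: SyntheticFieldSpec = dc_field(default_factory=reference_field_spec)
    regions: dict[str, SearchRegion] = dc_field(default_factory=dict)
    n_starts: int = 1000
    start_sampling_seed: int = 7
    step_size_intervals: Sequence[int] = (2,)
    rolling_window_lengths: Sequence[int] = (10,)
    max_steps: int = 100
    quality_threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not self.step_size_intervals or not self.rolling_window_lengths:
            raise ValueError("sweep grids must be non-empty")
        if not self.regions:
            self.regions = reference_regions(self.field_spec.canvas_width, self.field_spec.canvas_height)
        for name, region in self.regions.items():
            if (
                region.canvas_width != self.field_spec.canvas_width
                or region.canvas_height != self.field_spec.canvas_height
            ):
                raise InvalidRegionError(f"region {name!r} canvas does not match the field canvas")


@dataclass
class ExperimentResult:
    """Aggregates per (region, parameter combination) plus per-run records.

    ``summary`` has one row per region x combination with columns
    region, step_size_interval, rolling_window_length, n_starts,
    success_rate, mean_last_quality, mean_traversal_length,
    mean_evaluations; ``runs`` has one row per traversal with the start,
    end, success flag, last quality, traversal length and final window
    type — the raw material for start-point and endpoint maps.
    """

    summary: pd.DataFrame
    runs: pd.DataFrame

    def recompute_summary(self) -> pd.DataFrame:
        """Re-derive the aggregate table from the per-run records."""
        grouped = self.runs.groupby(
            ["region", "step_size_interval", "rolling_window_length"], as_index=False
        ).agg(
            n_starts=("success", "size"),
            success_rate=("success", "mean"),
            mean_last_quality=("last_quality", "mean"),
            mean_traversal_length=("traversal_length", "mean"),
            mean_evaluations=("n_evaluations", "mean"),
        )
        return grouped


def _region_seed(base_seed: int, region_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(region_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(cfg: ExperimentConfig, oracle: QualityOracle) -> ExperimentResult:
    """Run the full region x parameter sweep and aggregate the outcomes.

    Per-run failures from search preconditions are recorded as failed
    runs with a diagnostic, never aborting the sweep.
    """
    run_rows = []
    combos = list(itertools.product(cfg.step_size_intervals, cfg.rolling_window_lengths))

    for region_idx, (region_name, region) in enumerate(cfg.regions.items()):
        starts = sample_starts(region, cfg.n_starts, _region_seed(cfg.start_sampling_seed, region_idx))
        for interval, window_len in combos:
            for run_idx, start in enumerate(starts):
                row = {
                    "region": region_name,
                    "step_size_interval": interval,
                    "rolling_window_length": window_len,
                    "run_index": run_idx,
                    "start_x": start.x,
                    "start_y": start.y,
                }
                try:
                    result = run_search(
                        SearchConfig(
                            start=start,
                            step_size_interval=interval,
                            rolling_window_length=window_len,
                            max_steps=cfg.max_steps,
                            quality_threshold=cfg.quality_threshold,
                        ),
                        region,
                        oracle,
                    )
                except Exception as exc:  # diagnostic, not fatal to the sweep
                    row.update(
                        end_x=start.x, end_y=start.y, success=False,
                        last_quality=float("nan"), traversal_length=cfg.max_steps,
                        window_type="NONE", n_evaluations=0, diagnostic=str(exc),
                    )
                else:
                    row.update(
                        end_x=result.final_position.x,
                        end_y=result.final_position.y,
                        success=result.success,
                        last_quality=result.final_quality,
                        traversal_length=result.steps_taken,
                        window_type=result.final_window.label.value,
                        n_evaluations=result.n_evaluations,
                        diagnostic="isolated_start" if result.isolated_start else "",
                    )
                run_rows.append(row)

    runs = pd.DataFrame(run_rows)
    result = ExperimentResult(summary=pd.DataFrame(), runs=runs)
    result.summary = result.recompute_summary()
    return result


# ---------------------------------------------------------------------------
# trendlines
# ---------------------------------------------------------------------------


@dataclass
class TrendFit:
    """Least-squares degree-2 polynomial trend of an aggregate versus a
    hyperparameter. Coefficients are highest power first (a, b, c) for
    a*x^2 + b*x + c."""

    predictor: str
    coefficients: np.ndarray
    residuals: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, dtype=float))

    def is_nondecreasing(self, xs: Optional[Sequence[float]] = None, tol: float = 1e-12) -> bool:
        """Whether the fitted trend never decreases across the swept range
        (evaluated at the sorted sweep points by default)."""
        grid = np.sort(np.unique(self.xs if xs is None else np.asarray(xs, dtype=float)))
        fitted = self.predict(grid)
        return bool(np.all(np.diff(fitted) >= -tol))


def fit_trend(xs: Sequence[float], ys: Sequence[float], predictor: str = "x") -> TrendFit:
    """Degree-2 least-squares trendline through (xs, ys)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.ndim != 1:
        raise ValueError("xs and ys must be 1-D and equally long")
    if np.unique(xs).size < 3:
        raise ValueError("a degree-2 trend needs at least 3 distinct x values")
    coeffs = np.polyfit(xs, ys, deg=2)
    residuals = ys - np.polyval(coeffs, xs)
    return TrendFit(predictor=predictor, coefficients=coeffs, residuals=residuals, xs=xs, ys=ys)
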