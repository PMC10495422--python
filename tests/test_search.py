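"""The adaptive-step, memory-penalised traversal loop and its helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echonav import (
    FieldOracle,
    GridPosition,
    InvalidStartError,
    QualityField,
    RollingWindow,
    SearchConfig,
    SearchRegion,
    check_mean_decrease,
    check_revisit,
    point_in_region,
    run_search,
    select_best,
    update_step_size,
)

from conftest import make_smooth_field, random_quad_region, steepest_ascent_path


class TestUpdateStepSize:
    @pytest.mark.parametrize(
        "step,interval,revisit,mean_dec,expected",
        [
            (3, 2, True, False, 5),  # penalty grows the step
            (3, 2, False, True, 5),
            (3, 2, True, True, 5),
            (3, 2, False, False, 1),  # accepted move shrinks it
            (1, 2, False, False, 1),  # floored at the initial step size
            (5, 0, True, False, 5),  # interval 0 pins the step
            (5, 0, False, False, 5),
        ],
    )
    def test_rule(self, step, interval, revisit, mean_dec, expected):
        assert update_step_size(step, interval, revisit, mean_dec) == expected

    @given(step=st.integers(1, 50), interval=st.integers(0, 20), rev=st.booleans(), dec=st.booleans())
    @settings(max_examples=200, derandomize=True)
    def test_never_below_one(self, step, interval, rev, dec):
        assert update_step_size(step, interval, rev, dec) >= 1


class TestRollingWindow:
    def test_capacity_eviction_fifo(self):
        w = RollingWindow(2)
        w.push(GridPosition(1, 1), 0.1)
        w.push(GridPosition(2, 2), 0.9)
        w.push(GridPosition(3, 3), 0.5)
        assert w.positions() == [GridPosition(2, 2), GridPosition(3, 3)]
        assert len(w) == 2

    def test_zero_capacity_remembers_nothing(self):
        w = RollingWindow(0)
        w.push(GridPosition(1, 1), 0.5)
        assert len(w) == 0
        assert not check_revisit(w, GridPosition(1, 1))
        assert not check_mean_decrease(w, -1.0)

    def test_empty_mean_is_minus_inf(self):
        assert RollingWindow(3).mean() == float("-inf")


class TestChecks:
    def test_revisit_exact_match_only(self):
        w = RollingWindow(5)
        w.push(GridPosition(10, 10), 0.2)
        assert check_revisit(w, GridPosition(10, 10))
        assert not check_revisit(w, GridPosition(10, 11))
        assert not check_revisit(RollingWindow(5), GridPosition(0, 0))

    @pytest.mark.parametrize(
        "window_qs,capacity,q_new,expected",
        [
            ([0.5, 0.5], 3, 0.2, True),  # mean 0.5 -> 0.4
            ([0.5, 0.5], 3, 0.8, False),  # mean rises
            ([0.1, 0.9], 2, 0.5, False),  # eviction-aware: [0.9, 0.5] mean 0.7 > 0.5
            ([], 3, -1.0, False),  # empty window never reports a decrease
        ],
    )
    def test_mean_decrease(self, window_qs, capacity, q_new, expected):
        w = RollingWindow(capacity)
        for i, q in enumerate(window_qs):
            w.push(GridPosition(i, i), q)
        assert check_mean_decrease(w, q_new) is expected

    @given(
        qs=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=8),
        capacity=st.integers(1, 8),
        q_new=st.floats(-1, 1, allow_nan=False),
    )
    @settings(max_examples=300, derandomize=True)
    def test_mean_decrease_matches_brute_force(self, qs, capacity, q_new):
        """Oracle: rebuild both windows from scratch and compare raw means."""
        w = RollingWindow(capacity)
        for i, q in enumerate(qs):
            w.push(GridPosition(i, 0), q)
        kept = qs[-capacity:]
        after = (kept + [q_new])[-capacity:]
        expected = bool(kept) and (sum(after) / len(after)) < (sum(kept) / len(kept))
        assert check_mean_decrease(w, q_new) == expected


class TestSelectBest:
    def test_argmax(self):
        a, b, c = GridPosition(0, 0), GridPosition(1, 1), GridPosition(2, 2)
        assert select_best([(a, 0.1), (b, 0.9), (c, 0.3)]) == (b, 0.9)

    def test_tie_breaks_by_candidate_order(self):
        a, b = GridPosition(0, 0), GridPosition(1, 1)
        assert select_best([(a, 0.4), (b, 0.4)]) == (a, 0.4)

    def test_single_poor_candidate_still_selected(self):
        a = GridPosition(0, 0)
        assert select_best([(a, -0.9)]) == (a, -0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])


def flat_field(width, height, value):
    q = np.full((height, width), value, dtype=float)
    return QualityField(quality=q, labels=np.zeros_like(q, dtype=np.int8))


class _StubRegion:
    """Region double admitting an explicit pixel set; used to exercise
    the isolated-start branch, which no 4-vertex lattice polygon with
    boundary-inclusive membership can reach."""

    def __init__(self, pixels):
        self.pixels = set(pixels)

    def contains(self, p):
        return tuple(p) in self.pixels

    def contains_many(self, xs, ys):
        return np.array([(x, y) in self.pixels for x, y in zip(xs, ys)])


class TestRunSearch:
    def test_immediate_success_when_start_meets_threshold(self, big_square):
        oracle = FieldOracle(flat_field(200, 200, 0.97))
        r = run_search(SearchConfig(start=GridPosition(50, 50)), big_square, oracle)
        assert r.success and r.steps_taken == 0
        assert r.path == [GridPosition(50, 50)]
        assert r.n_evaluations == 1

    def test_uniformly_bad_field_fails_at_exactly_max_steps(self, big_square):
        oracle = FieldOracle(flat_field(200, 200, -0.9))
        r = run_search(SearchConfig(start=GridPosition(50, 50), max_steps=100), big_square, oracle)
        assert not r.success
        assert r.steps_taken == 100
        assert len(r.path) == 101
        assert len(r.qualities) == len(r.path)
        assert len(r.step_sizes) == 100

    def test_start_outside_region_rejected(self, big_square):
        oracle = FieldOracle(flat_field(200, 200, -0.9))
        with pytest.raises(InvalidStartError):
            run_search(SearchConfig(start=GridPosition(300, 300)), big_square, oracle)

    def test_isolated_start_fails_with_diagnostic(self):
        oracle = FieldOracle(flat_field(20, 20, -0.9))
        region = _StubRegion({(5, 5)})
        r = run_search(SearchConfig(start=GridPosition(5, 5)), region, oracle)
        assert not r.success and r.isolated_start
        assert r.steps_taken == 0

    def test_empty_group_shrinks_step_within_iteration(self):
        # only the start and its four step-1 neighbours exist; force the
        # step to grow via revisits, then observe it recover to 1
        pixels = {(5, 5), (5, 4), (5, 6), (4, 5), (6, 5)}
        region = _StubRegion(pixels)
        oracle = FieldOracle(flat_field(20, 20, -0.9))
        r = run_search(
            SearchConfig(start=GridPosition(5, 5), step_size_interval=3, rolling_window_length=10, max_steps=20),
            region,
            oracle,
        )
        assert not r.success
        assert all(s == 1 for s in r.step_sizes)  # larger steps always overshoot and shrink back
        assert all(tuple(p) in pixels for p in r.path)

    def test_greedy_limit_equals_plain_hill_climbing(self, big_square):
        """interval=0, window=0 reduces the loop to steepest-ascent
        4-neighbour hill climbing (independent implementation)."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            field = make_smooth_field(rng, 40, 40)
            region = SearchRegion.from_vertex_list([(0, 0), (39, 0), (39, 39), (0, 39)], 40, 40)
            start = GridPosition(int(rng.integers(0, 40)), int(rng.integers(0, 40)))
            cfg = SearchConfig(start=start, step_size_interval=0, rolling_window_length=0, max_steps=60)
            got = run_search(cfg, region, FieldOracle(field)).path
            want = steepest_ascent_path(field.quality, region, start, 60, cfg.quality_threshold)
            assert got == want

    def test_randomized_invariants(self):
        """Termination, confinement, step-size floor and bookkeeping over
        random fields, regions and configurations."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            w, h = int(rng.integers(20, 60)), int(rng.integers(20, 60))
            field = make_smooth_field(rng, w, h)
            region = random_quad_region(rng, w, h)
            start = _random_inside(rng, region)
            if start is None:
                continue
            cfg = SearchConfig(
                start=start,
                step_size_interval=int(rng.integers(0, 6)),
                rolling_window_length=int(rng.integers(0, 15)),
                max_steps=int(rng.integers(1, 60)),
                quality_threshold=float(rng.uniform(0.5, 1.0)),
            )
            r = run_search(cfg, region, FieldOracle(field))
            assert r.steps_taken <= cfg.max_steps
            assert len(r.path) == r.steps_taken + 1
            assert all(point_in_region(p, region) for p in r.path)
            assert all(s >= 1 for s in r.step_sizes)
            if r.success:
                assert r.final_quality >= cfg.quality_threshold

    def test_seeded_determinism(self, ref_oracle, ref_regions):
        cfg = SearchConfig(start=GridPosition(700, 500), step_size_interval=2, rolling_window_length=10)
        a = run_search(cfg, ref_regions["left_torso"], ref_oracle)
        b = run_search(cfg, ref_regions["left_torso"], ref_oracle)
        assert a.path == b.path and a.qualities == b.qualities and a.step_sizes == b.step_sizes

    def test_escape_property_on_reference_field(self, ref_oracle, ref_regions):
        """From a background start, the greedy limit stalls on a noise-made
        local optimum while an adaptive configuration escapes to the band."""
        region = ref_regions["left_torso"]
        start = GridPosition(560, 470)
        greedy = run_search(
            SearchConfig(start=start, step_size_interval=0, rolling_window_length=0), region, ref_oracle
        )
        adaptive = run_search(
            SearchConfig(start=start, step_size_interval=2, rolling_window_length=10), region, ref_oracle
        )
        assert not greedy.success
        assert adaptive.success


def _random_inside(rng, region):
    minx, miny, maxx, maxy = region.bounds()
    for _ in range(200):
        p = GridPosition(int(rng.integers(minx, maxx + 1)), int(rng.integers(miny, maxy + 1)))
        if point_in_region(p, region):
            return p
    return None
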