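"""The echo-window search algorithm: adaptive-step, memory-penalised traversal.

Each iteration scores the current position; if it meets the quality
threshold the traversal ends in success. Otherwise the four positions one
step to the north, south, east and west (the *step group*) are scored,
the best becomes the next start, and two checks against a fixed-capacity
FIFO of recently visited (position, quality) pairs — the *rolling
window* — decide whether the step size grows (the best candidate was
visited before, or it drags the window's mean quality down: a penalty,
so jump further next time) or shrinks (progress: focus locally). The
step size starts at 1 and never falls below 1. Positions at which a
traversal terminates are never pushed into the rolling window, so its
contents can all be read as past mistakes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field as dc_field

from .geometry import GridPosition, SearchRegion, point_in_region, step_group
from .oracle import QualityOracle, WindowType, WINDOW_NONE

__all__ = [
    "SearchConfig",
    "RollingWindow",
    "TraversalResult",
    "InvalidStartError",
    "update_step_size",
    "check_revisit",
    "check_mean_decrease",
    "select_best",
    "run_search",
]


class InvalidStartError(ValueError):
    """Raised when the configured start lies outside the search region."""


@dataclass(frozen=True)
class SearchConfig:
    """User-set traversal hyperparameters.

    ``step_size_interval`` is the amount the step size grows after a
    penalised move or shrinks after an accepted one (0 pins the step at
    1); ``rolling_window_length`` is the short-term-memory capacity
    (0 disables the memory entirely).
    """

    start: GridPosition
    step_size_interval: int = 2
    rolling_window_length: int = 10
    max_steps: int = 100
    quality_threshold: float = 0.95

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", GridPosition(*self.start))
        if self.step_size_interval < 0:
            raise ValueError("step_size_interval must be >= 0")
        if self.rolling_window_length < 0:
            raise ValueError("rolling_window_length must be >= 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not (0.0 < self.quality_threshold <= 1.0):
            raise ValueError("quality_threshold must lie in (0, 1]")


class RollingWindow:
    """Fixed-capacity FIFO of (position, quality) pairs, newest last.

    Pushing at capacity evicts the oldest entry. Capacity 0 is a valid
    degenerate window that remembers nothing.
    """

    def __init__(self, capacity: int):
        if capacity < 0:
            raise ValueError("capacity must be >= 0")
        self.capacity = capacity
        self._entries: deque[tuple[GridPosition, float]] = deque(maxlen=capacity)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def push(self, p: GridPosition, quality: float) -> None:
        self._entries.append((GridPosition(*p), float(quality)))

    def mean(self) -> float:
        """Arithmetic mean of stored qualities; -inf when empty so that any
        comparison treats an empty memory as no information."""
        if not self._entries:
            return float("-inf")
        return sum(q for _, q in self._entries) / len(self._entries)

    def positions(self) -> list[GridPosition]:
        return [p for p, _ in self._entries]

    def qualities(self) -> list[float]:
        return [q for _, q in self._entries]


@dataclass
class TraversalResult:
    """Outcome of one traversal: the path of start positions (first entry
    the configured start, last the terminal position), per-position
    qualities, per-move step sizes, and the window type at the end."""

    success: bool
    path: list[GridPosition]
    qualities: list[float]
    step_sizes: list[int]
    final_window: WindowType
    steps_taken: int
    n_evaluations: int = 0
    revisit_flags: list[bool] = dc_field(default_factory=list)
    mean_decrease_flags: list[bool] = dc_field(default_factory=list)
    isolated_start: bool = False

    @property
    def final_position(self) -> GridPosition:
        return self.path[-1]

    @property
    def final_quality(self) -> float:
        return self.qualities[-1]

    def to_dict(self) -> dict:
        return {
            "success": self.success,
            "path": [list(p) for p in self.path],
            "qualities": self.qualities,
            "step_sizes": self.step_sizes,
            "final_window": self.final_window.label.value,
            "final_window_probability": self.final_window.probability,
            "steps_taken": self.steps_taken,
            "n_evaluations": self.n_evaluations,
            "revisit_flags": self.revisit_flags,
            "mean_decrease_flags": self.mean_decrease_flags,
            "isolated_start": self.isolated_start,
        }


def update_step_size(current_step: int, interval: int, revisit: bool, mean_decreased: bool) -> int:
    """Next step size: grow by ``interval`` after a penalised move (revisit
    or mean decrease), otherwise shrink by ``interval``, floored at 1."""
    if current_step < 1:
        raise ValueError("current_step must be >= 1")
    if interval < 0:
        raise ValueError("interval must be >= 0")
    if revisit or mean_decreased:
        return current_step + interval
    return max(1, current_step - interval)


def check_revisit(w: RollingWindow, p: GridPosition) -> bool:
    """True iff some remembered entry has exactly p's coordinates."""
    p = GridPosition(*p)
    return any(stored == p for stored in w.positions())


def check_mean_decrease(w: RollingWindow, q_new: float) -> bool:
    """True iff appending ``q_new`` (respecting capacity eviction) would
    lower the window's mean quality. An empty window never reports a
    decrease."""
    qs = w.qualities()
    if not qs:
        return False
    mean_before = sum(qs) / len(qs)
    after = qs + [float(q_new)]
    if w.capacity and len(after) > w.capacity:
        after = after[len(after) - w.capacity:]
    mean_after = sum(after) / len(after)
    return mean_after < mean_before


def select_best(candidates: list[tuple[GridPosition, float]]) -> tuple[GridPosition, float]:
    """The candidate with maximal quality; ties keep the earliest candidate
    (N before S before E before W)."""
    if not candidates:
        raise ValueError("select_best needs at least one candidate")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[1] > best[1]:
            best = cand
    return best


def run_search(cfg: SearchConfig, region: SearchRegion, oracle: QualityOracle) -> TraversalResult:
    """Run one traversal of the echo-window search loop.

    Per iteration: (1) score the current position; stop with success if it
    meets the threshold (terminal positions are never pushed into the
    rolling window); (2) score the in-region step group at the current
    step size; (3) take the best candidate; (4) run the revisit and
    mean-decrease checks against the rolling window *before* pushing the
    new entry; (5) update the step size; (6) push the selected pair into
    the window; (7) move there. The run fails once ``max_steps`` moves
    elapse without meeting the threshold, or immediately when even a
    step-1 group is empty (isolated start).

    When the step group is empty because the current step overshoots the
    region on all four sides, the step size is shrunk by the interval
    (floor 1) and the group regenerated within the same iteration.
    """
    if not point_in_region(cfg.start, region):
        raise InvalidStartError(f"start {tuple(cfg.start)} lies outside the search region")

    window = RollingWindow(cfg.rolling_window_length)
    pos = cfg.start
    step = 1  # the step size is initialised as 1
    n_evals = 0

    path = [pos]
    qualities: list[float] = []
    step_sizes: list[int] = []
    revisit_flags: list[bool] = []
    mean_decrease_flags: list[bool] = []
    success = False
    isolated = False
    final_window: WindowType = WINDOW_NONE

    for _ in range(cfg.max_steps + 1):
        quality, wtype = oracle.evaluate(pos)
        n_evals += 1
        qualities.append(quality)
        final_window = wtype
        if quality >= cfg.quality_threshold:
            success = True
            break
        if len(path) > cfg.max_steps:
            break  # step cap reached: failure

        candidates = step_group(pos, step, region)
        while not candidates and step > 1:
            # overshoot on all four sides: shrink and retry this iteration
            step = max(1, step - cfg.step_size_interval) if cfg.step_size_interval >= 1 else 1
            candidates = step_group(pos, step, region)
        if not candidates:
            isolated = True
            break

        scored = []
        for cand in candidates:
            q_cand, _ = oracle.evaluate(cand)
            n_evals += 1
            scored.append((cand, q_cand))
        best_pos, best_q = select_best(scored)

        revisit = check_revisit(window, best_pos)
        mean_dec = check_mean_decrease(window, best_q)
        next_step = update_step_size(step, cfg.step_size_interval, revisit, mean_dec)
        window.push(best_pos, best_q)

        step_sizes.append(step)
        revisit_flags.append(revisit)
        mean_decrease_flags.append(mean_dec)
        path.append(best_pos)
        pos = best_pos
        step = next_step

    return TraversalResult(
        success=success,
        path=path,
        qualities=qualities,
        step_sizes=step_sizes,
        final_window=final_window,
        steps_taken=len(path) - 1,
        n_evaluations=n_evals,
        revisit_flags=revisit_flags,
        mean_decrease_flags=mean_decrease_flags,
        isolated_start=isolated,
    )
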