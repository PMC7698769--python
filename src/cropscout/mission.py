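"""Mission loop and energy model.

Runs a scouting policy to a target coverage, tracks battery drain and
recharge events, and produces the final whole-field health map.

The battery drains 5% per zone-step from a 100% charge; whenever it falls to
the 30% threshold after a step it is swapped/recharged to 100% before the
next step.  The charge count is 1 (the initial battery) plus the number of
recharge events.  Relocation flights to the nearest unsampled zone cost one
drain step per zone of Chebyshev distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid_core import (
    FieldGrid,
    HEALTHY,
    UNHEALTHY,
    extract_window,
    partition,
)
from .neighbor_models import ReferenceSet, ScoutingModels
from .rl_pathfinder import (
    RLDataset,
    chebyshev,
    encode_state,
    nearest_unvisited,
    random_path,
    select_action,
    select_action_utility,
)
from .window_fill import fill_window
from .local_baseline import dilate_map, local_features, local_select_action

POLICIES = ("whole_field", "local_field", "random", "exhaustive", "non_scouting")


@dataclass(frozen=True)
class BatteryModel:
    """Empirical battery behavior: 5%/step drain, recharge at the 30% floor."""

    capacity: float = 100.0
    drain_per_step: float = 5.0
    recharge_threshold: float = 30.0
    recharge_to: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.drain_per_step < self.capacity:
            raise ValueError("drain_per_step must be in (0, capacity)")
        if self.recharge_threshold >= self.capacity:
            raise ValueError("recharge threshold must be below capacity")


def battery_trace(n_steps: int, battery: BatteryModel | None = None) -> tuple[list[float], int]:
    """Battery % after each of ``n_steps`` zone-steps, and the charge count.

    A recharge fires whenever the post-step level is at or below the
    threshold; the battery returns to full before the next step.
    """
    if battery is None:
        battery = BatteryModel()
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    level = battery.capacity
    charges = 1
    trace: list[float] = []
    for _ in range(n_steps):
        level -= battery.drain_per_step
        trace.append(level)
        if level <= battery.recharge_threshold:
            level = battery.recharge_to
            charges += 1
    return trace, charges


@dataclass
class MissionResult:
    """Everything one flight produced."""

    policy: str
    path: list[tuple[int, int]]
    battery: list[float]
    charges: int
    predicted_map: np.ndarray
    coverage: float
    logs: list[dict] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.battery)

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "path": [list(p) for p in self.path],
            "battery": self.battery,
            "charges": self.charges,
            "coverage": self.coverage,
            "predicted_map": self.predicted_map.tolist(),
        }


def boustrophedon(grid: FieldGrid) -> list[tuple[int, int]]:
    """Serpentine exhaustive path: row 0 west-to-east, row 1 back, ..."""
    path = []
    for r in range(grid.rows):
        cols = range(grid.cols) if r % 2 == 0 else range(grid.cols - 1, -1, -1)
        path.extend((r, c) for c in cols)
    return path


def final_whole_field_map(
    grid: FieldGrid,
    visited: set,
    center: tuple[int, int],
    models: ScoutingModels,
    ref: ReferenceSet,
) -> np.ndarray:
    """Extrapolate the complete field map from the flight path.

    Same fill algorithm, run once over the full-field partition with a window
    wide enough to cover every zone from the UAS's final position.
    """
    part = partition(visited, grid.shape)
    w = 2 * max(grid.rows, grid.cols) + 1
    win = extract_window(grid, part, center, w)
    filled = fill_window(win, models, ref)
    out = np.zeros(grid.shape, dtype=np.int8)
    for r in range(grid.rows):
        for c in range(grid.cols):
            wr, wc = filled.to_window(r, c)
            out[r, c] = int(filled.labels[wr, wc])
    return out


def run_mission(
    policy: str,
    grid: FieldGrid,
    coverage: float,
    rng: np.random.Generator,
    models: ScoutingModels | None = None,
    ref: ReferenceSet | None = None,
    rl_dataset: RLDataset | None = None,
    battery: BatteryModel | None = None,
    window_size: int = 7,
    adjacency: int = 8,
    action_rule: str = "discrepancy",
) -> MissionResult:
    """Fly one mission and return the path, battery trace and final map.

    Policies: ``whole_field`` (KNN-RL over filled prediction windows, then a
    whole-field fill), ``local_field`` (last-zone-features RL, then recursive
    dilation), ``random`` (random walk, whole-field fill), ``exhaustive``
    (boustrophedon over every zone; its map is the ground truth) and
    ``non_scouting`` (no flight; every zone treated as unhealthy).
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if battery is None:
        battery = BatteryModel()

    if policy == "non_scouting":
        pred = np.full(grid.shape, UNHEALTHY, dtype=np.int8)
        return MissionResult(policy, [], [], 1, pred, 0.0)

    if policy == "exhaustive":
        if grid.truth_labels is None:
            raise ValueError("exhaustive scouting needs truth labels")
        path = boustrophedon(grid)
        trace, charges = battery_trace(len(path), battery)
        return MissionResult(policy, path, trace, charges, grid.truth_labels.copy(), 1.0)

    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if models is None or ref is None:
        raise ValueError(f"{policy} scouting needs trained models and a reference set")
    if policy in ("whole_field", "local_field") and rl_dataset is None:
        raise ValueError(f"{policy} needs an RL dataset (build_rl_dataset)")

    models.attach_field(grid)
    n_target = math.ceil(coverage * grid.n_zones)

    if policy == "random":
        path = random_path(grid, coverage, rng, adjacency)
        visited = set(path)
        n_steps = _path_steps(path)
        pred = final_whole_field_map(grid, visited, path[-1], models, ref)
        trace, charges = battery_trace(n_steps, battery)
        return MissionResult(policy, path, trace, charges, pred, len(visited) / grid.n_zones)

    # RL policies share the stepping loop
    border = grid.border_zones()
    current = border[rng.integers(len(border))]
    path = [current]
    visited = {current}
    logs: list[dict] = []
    n_steps = 1
    while len(visited) < n_target:
        action = None
        if policy == "whole_field":
            part = partition(visited, grid.shape)
            win = extract_window(grid, part, current, window_size)
            filled = fill_window(win, models, ref)
            cov = len(visited) / grid.n_zones
            if action_rule == "discrepancy":
                action = select_action(filled, rl_dataset, models, visited, cov, adjacency)
            elif action_rule == "utility":
                action = select_action_utility(
                    filled, rl_dataset, models, visited, cov, adjacency
                )
            else:
                raise ValueError(f"unknown action rule {action_rule!r}")
        else:  # local_field
            feats = local_features(grid.zone_images[current])
            action = local_select_action(
                feats, rl_dataset, visited, current, grid.shape, adjacency
            )

        if action is None:  # boxed in: relocate to the nearest unsampled zone
            nxt = nearest_unvisited(current, visited, grid.shape)
            n_steps += chebyshev(current, nxt)
            logs.append({"step": len(path), "relocate": True, "to": nxt})
        else:
            nxt = action.apply(current)
            n_steps += 1
            logs.append({"step": len(path), "action": action.name, "to": nxt})
        current = nxt
        path.append(current)
        visited.add(current)

    if policy == "whole_field":
        pred = final_whole_field_map(grid, visited, current, models, ref)
    else:
        partial = np.full(grid.shape, np.nan)
        for r, c in visited:
            partial[r, c] = float(grid.truth_labels[r, c])
        pred = dilate_map(partial)

    trace, charges = battery_trace(n_steps, battery)
    return MissionResult(
        policy, path, trace, charges, pred, len(visited) / grid.n_zones, logs
    )


def _path_steps(path: list[tuple[int, int]]) -> int:
    """Zone-steps including relocation distance (first zone costs one step)."""
    steps = 1
    for a, b in zip(path, path[1:]):
        steps += max(1, chebyshev(a, b))
    return steps
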