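"""KNN-based reinforcement-learning path planner.

The planner is trained on simulated random flights: for every transition of
every random path we store the encoded window state, the action taken, the
realized utility gain (improvement of window-map accuracy) and the realized
health label of the destination zone.  At flight time the k = 11 most
similar prior states are retrieved (L2 on the encoded vectors) and the UAS
flies toward the candidate action whose retrieved label estimate disagrees
most with the spatial-ensemble prediction — the zone the system understands
least.  An alternative rule flies toward the largest mean retrieved utility
gain.

State encoding: the flattened ground-truth layer (1 healthy / 0 unhealthy /
0.5 where not observed) concatenated with the flattened predicted-probability
layer, plus the current coverage fraction — length ``2 w^2 + 1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid_core import (
    Direction,
    FieldGrid,
    PredictionWindow,
    Status,
    extract_window,
    flight_neighbors,
    partition,
)
from .neighbor_models import DIRECTION_ORDER, ReferenceSet, ScoutingModels
from .window_fill import fill_window, window_accuracy

DEFAULT_K: int = 11
#: Sentinel for unobserved zones in the encoded state (uninformative midpoint).
SENTINEL: float = 0.5


# ---------------------------------------------------------------------------
# Random flight paths


def chebyshev(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def nearest_unvisited(
    current: tuple[int, int], visited: set, grid_shape: tuple[int, int]
) -> tuple[int, int]:
    """Closest unsampled zone by Chebyshev distance; ties by row-major order."""
    rows, cols = grid_shape
    best = None
    best_d = math.inf
    for r in range(rows):
        for c in range(cols):
            if (r, c) in visited:
                continue
            d = chebyshev(current, (r, c))
            if d < best_d:
                best, best_d = (r, c), d
    if best is None:
        raise RuntimeError("no unvisited zone remains")
    return best


def random_path(
    grid: FieldGrid,
    coverage: float,
    rng: np.random.Generator,
    adjacency: int = 8,
) -> list[tuple[int, int]]:
    """Random scouting path reaching the target coverage.

    Starts at a uniformly random border zone; every step moves to a uniformly
    random unvisited flight-neighbor.  When the UAS is boxed in (no unvisited
    neighbor) it relocates to the nearest unsampled zone.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    coverage = min(coverage, 1.0)
    n_target = math.ceil(coverage * grid.n_zones)
    border = grid.border_zones()
    current = border[rng.integers(len(border))]
    path = [current]
    visited = {current}
    while len(path) < n_target:
        options = [
            coord
            for _, coord in flight_neighbors(current, grid.shape, adjacency)
            if coord not in visited
        ]
        if options:
            current = options[rng.integers(len(options))]
        else:
            current = nearest_unvisited(current, visited, grid.shape)
        path.append(current)
        visited.add(current)
    return path


# ---------------------------------------------------------------------------
# State encoding and dataset


def encode_state(window: PredictionWindow, coverage_fraction: float) -> np.ndarray:
    """Fixed-length vector for a *filled* window: ``2 w^2 + 1`` entries.

    Layer 1 is observed ground truth (sentinel 0.5 where not observed, also
    at out-of-field slots); layer 2 is the predicted probability of healthy;
    the last entry is the mission coverage fraction.
    """
    inb = window.in_bounds
    if np.any(inb & (window.status != Status.VISIBLE)):
        raise ValueError("encode_state requires a fully filled window")
    truth_layer = np.where(window.truth_mask, window.labels, SENTINEL)
    pred_layer = np.where(inb & ~np.isnan(window.probs), window.probs, SENTINEL)
    return np.concatenate(
        [truth_layer.ravel(), pred_layer.ravel(), [float(coverage_fraction)]]
    )


@dataclass
class StateRecord:
    """One RL training example: state, action, realized outcome."""

    encoded_state: np.ndarray
    action: Direction
    utility_gain: float  # raw (un-normalized) accuracy improvement
    next_label: int  # realized truth label of the destination zone


@dataclass
class RLDataset:
    """A bank of prior (state, action, outcome) experiences.

    Utility gains are normalized by the maximum absolute gain in the dataset
    (mapping to [-1, 1]) when queried through :meth:`gains`.
    """

    records: list[StateRecord]
    window_size: int
    coverage_rate: float
    k: int = DEFAULT_K
    _states: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.records and self.k > len(self.records):
            raise ValueError(f"k={self.k} exceeds dataset size {len(self.records)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def states(self) -> np.ndarray:
        if self._states is None:
            self._states = np.stack([r.encoded_state for r in self.records])
        return self._states

    @property
    def actions(self) -> np.ndarray:
        return np.array([DIRECTION_ORDER.index(r.action) for r in self.records])

    @property
    def next_labels(self) -> np.ndarray:
        return np.array([r.next_label for r in self.records], dtype=float)

    def gains(self) -> np.ndarray:
        """Normalized utility gains in [-1, 1]."""
        raw = np.array([r.utility_gain for r in self.records])
        m = np.max(np.abs(raw)) if len(raw) else 0.0
        return raw / m if m > 0 else raw

    # -- persistence (CSV + JSON sidecar) ----------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(self.states)
        df.columns = [f"s{i}" for i in range(df.shape[1])]
        df["action"] = [r.action.name for r in self.records]
        df["utility_gain"] = [r.utility_gain for r in self.records]
        df["next_label"] = [r.next_label for r in self.records]
        df.to_csv(path, index=False)
        sidecar = {
            "window_size": self.window_size,
            "coverage_rate": self.coverage_rate,
            "k": self.k,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RLDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        state_cols = [c for c in df.columns if c.startswith("s")]
        records = [
            StateRecord(
                encoded_state=row[state_cols].to_numpy(dtype=float),
                action=Direction[row["action"]],
                utility_gain=float(row["utility_gain"]),
                next_label=int(row["next_label"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records=records, **meta)


def build_rl_dataset(
    train_fields: list[FieldGrid],
    coverages,
    window_sizes,
    n_paths: int,
    models: ScoutingModels,
    ref: ReferenceSet,
    rng: np.random.Generator,
    k: int = DEFAULT_K,
    adjacency: int = 8,
    encoding: str = "window",
) -> dict[tuple[float, int], RLDataset]:
    """Simulate random flights and harvest one StateRecord per transition.

    For every (coverage, window size) combination, ``n_paths`` random paths
    are flown across the training fields (cycled).  Each transition records
    the filled-window state before the step, the action taken (relocations
    mapped to the compass direction of their displacement), the realized
    utility gain (window accuracy after minus before) and the destination
    zone's truth label.

    ``encoding="local"`` swaps the window encoding for last-zone image
    features (the local-field baseline's state).
    """
    from .local_baseline import local_features

    if not getattr(models.ensemble, "trained", False):
        raise RuntimeError("train the directional predictors first")
    out: dict[tuple[float, int], RLDataset] = {}
    for coverage in np.atleast_1d(coverages):
        coverage = float(coverage)
        for w in np.atleast_1d(window_sizes):
            w = int(w)
            records: list[StateRecord] = []
            for p_idx in range(n_paths):
                grid = train_fields[p_idx % len(train_fields)]
                models.attach_field(grid)
                path = random_path(grid, coverage, rng, adjacency)
                records.extend(
                    _harvest_path(path, grid, w, models, ref, encoding, local_features)
                )
            out[(coverage, w)] = RLDataset(
                records=records, window_size=w, coverage_rate=coverage, k=k
            )
    return out


def _harvest_path(path, grid, w, models, ref, encoding, local_features):
    n = grid.n_zones
    records = []
    visited: set = set()
    prev_acc = None
    prev_state = None
    for t, coord in enumerate(path):
        visited.add(coord)
        part = partition(visited, grid.shape)
        win = extract_window(grid, part, coord, w)
        filled = fill_window(win, models, ref)
        acc = window_accuracy(filled, grid.truth_labels)
        if encoding == "window":
            state = encode_state(filled, len(visited) / n)
        elif encoding == "local":
            state = local_features(grid.zone_images[coord])
        else:
            raise ValueError(f"unknown encoding {encoding!r}")
        if t > 0:
            dr = coord[0] - path[t - 1][0]
            dc = coord[1] - path[t - 1][1]
            records.append(
                StateRecord(
                    encoded_state=prev_state,
                    action=Direction.from_delta(dr, dc),
                    utility_gain=acc - prev_acc,
                    next_label=int(grid.truth_labels[coord]),
                )
            )
        prev_acc = acc
        prev_state = state
    return records


# ---------------------------------------------------------------------------
# Action selection


def knn_indices(states: np.ndarray, query: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest records by L2 distance (stable on ties)."""
    d = np.sum((states - query) ** 2, axis=1)
    return np.argsort(d, kind="stable")[:k]


def _candidates(window: PredictionWindow, visited: set, adjacency: int):
    out = []
    for d, coord in flight_neighbors(window.center, window.grid_shape, adjacency):
        if coord not in visited:
            out.append((d, coord))
    return out


def select_action(
    window: PredictionWindow,
    dataset: RLDataset,
    models: ScoutingModels,
    visited: set,
    coverage_fraction: float,
    adjacency: int = 8,
) -> Direction | None:
    """Largest-disagreement rule: fly where KNN and the spatial ensemble differ most.

    Retrieves the k most similar prior states; for each candidate action the
    KNN estimate is the mean realized destination label among retrieved
    records that took that action, the model estimate is the filled window's
    ensemble probability at the destination, and the chosen action maximizes
    their absolute difference.  Candidates without retrieved evidence rank
    below any candidate with evidence; ties resolve in fixed compass order.
    Returns ``None`` when no unvisited flight-neighbor exists (relocation
    signal for the mission layer).
    """
    cands = _candidates(window, visited, adjacency)
    if not cands:
        return None
    if len(dataset) < dataset.k:
        raise ValueError("RL dataset smaller than k")
    query = encode_state(window, coverage_fraction)
    idx = knn_indices(dataset.states, query, dataset.k)
    actions = dataset.actions[idx]
    labels = dataset.next_labels[idx]

    best, best_score = None, -math.inf
    for d, coord in _ordered(cands):
        wloc = window.to_window(*coord)
        model_est = float(window.probs[wloc])
        mask = actions == DIRECTION_ORDER.index(d)
        score = abs(float(labels[mask].mean()) - model_est) if mask.any() else -1.0
        if score > best_score:
            best, best_score = d, score
    return best


def select_action_utility(
    window: PredictionWindow,
    dataset: RLDataset,
    models: ScoutingModels,
    visited: set,
    coverage_fraction: float,
    adjacency: int = 8,
    query: np.ndarray | None = None,
) -> Direction | None:
    """Alternative rule: fly toward the highest mean retrieved utility gain."""
    cands = _candidates(window, visited, adjacency)
    if not cands:
        return None
    if len(dataset) < dataset.k:
        raise ValueError("RL dataset smaller than k")
    if query is None:
        query = encode_state(window, coverage_fraction)
    idx = knn_indices(dataset.states, query, dataset.k)
    actions = dataset.actions[idx]
    gains = dataset.gains()[idx]

    best, best_score = None, -math.inf
    for d, _coord in _ordered(cands):
        mask = actions == DIRECTION_ORDER.index(d)
        score = float(gains[mask].mean()) if mask.any() else -math.inf
        if score > best_score:
            best, best_score = d, score
    if best is None:  # no candidate had evidence: fixed-order fallback
        best = _ordered(cands)[0][0]
    return best


def _ordered(cands):
    return sorted(cands, key=lambda dc: DIRECTION_ORDER.index(dc[0]))
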