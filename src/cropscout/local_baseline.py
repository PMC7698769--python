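"""Local-field RL baseline.

The baseline policy sees only the image of the last visited zone: its RL
state is a small vector of local image properties (mean ExG, mean HSV
saturation, channel means).  Map completion happens once, after the mission,
by recursive dilation: every unlabeled zone with at least one labeled
8-neighbor receives the consensus (majority) label of those neighbors, ties
going to healthy; passes are synchronous and repeat until the map is full.

Dilation reinforces clusters: a solid block of one label expands faster than
the same number of scattered seeds, which is exactly the failure mode this
baseline exhibits on fields with large stressed patches.
"""

from __future__ import annotations

import numpy as np
from matplotlib.colors import rgb_to_hsv

from .grid_core import HEALTHY, UNHEALTHY
from .rl_pathfinder import RLDataset, knn_indices
from .vegetation import zone_exg

LOCAL_FEATURE_NAMES: tuple[str, ...] = ("exg_mean", "saturation_mean", "r_mean", "g_mean", "b_mean")


def local_features(tile: np.ndarray) -> np.ndarray:
    """Image-property state vector of one zone tile (fixed length 5)."""
    tile = np.asarray(tile, dtype=float)
    if tile.size == 0:
        raise ValueError("empty tile")
    hsv = rgb_to_hsv(tile / 255.0)
    return np.array(
        [
            zone_exg(tile),
            hsv[..., 1].mean(),
            tile[..., 0].mean() / 255.0,
            tile[..., 1].mean() / 255.0,
            tile[..., 2].mean() / 255.0,
        ]
    )


def dilate_map(
    partial: np.ndarray, grid_shape: tuple[int, int] | None = None, tie_label: int = HEALTHY
) -> np.ndarray:
    """Complete a partial label map by synchronous majority dilation.

    ``partial`` is a float array with NaN marking unlabeled zones.  Each pass
    labels every unlabeled zone that has at least one labeled 8-neighbor with
    the majority label of those neighbors (ties -> ``tie_label``); zones
    labeled in a pass only participate from the next pass on.
    """
    arr = np.asarray(partial, dtype=float)
    if grid_shape is not None and arr.shape != tuple(grid_shape):
        raise ValueError("partial map shape does not match grid_shape")
    if np.all(np.isnan(arr)):
        raise ValueError("cannot dilate an entirely unlabeled map")
    rows, cols = arr.shape
    out = arr.copy()
    while np.any(np.isnan(out)):
        labeled = ~np.isnan(out)
        healthy = np.where(labeled, out == HEALTHY, False).astype(int)
        unhealthy = np.where(labeled, out == UNHEALTHY, False).astype(int)
        n_h = _ring_sum(healthy)
        n_u = _ring_sum(unhealthy)
        target = ~labeled & ((n_h + n_u) > 0)
        if not np.any(target):
            raise RuntimeError("disconnected map cannot be completed")
        if tie_label == HEALTHY:
            new_label = np.where(n_h >= n_u, float(HEALTHY), float(UNHEALTHY))
        else:
            new_label = np.where(n_u >= n_h, float(UNHEALTHY), float(HEALTHY))
        out = np.where(target, new_label, out)
    return out.astype(np.int8)


def _ring_sum(mask: np.ndarray) -> np.ndarray:
    """Count of set 8-neighbors for every cell."""
    rows, cols = mask.shape
    padded = np.pad(mask, 1)
    total = np.zeros((rows, cols), dtype=int)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            if dr == 1 and dc == 1:
                continue
            total += padded[dr : dr + rows, dc : dc + cols]
    return total


def local_select_action(
    features: np.ndarray,
    local_dataset: RLDataset,
    visited: set,
    center: tuple[int, int],
    grid_shape: tuple[int, int],
    adjacency: int = 8,
):
    """KNN utility-gain action selection on the local feature encoding.

    Same retrieval/argmax machinery as the whole-field utility rule, but the
    state is the last zone's image features rather than a prediction window.
    Returns ``None`` when no unvisited flight-neighbor exists.
    """
    import math

    from .grid_core import flight_neighbors
    from .neighbor_models import DIRECTION_ORDER

    cands = [
        (d, coord)
        for d, coord in flight_neighbors(center, grid_shape, adjacency)
        if coord not in visited
    ]
    if not cands:
        return None
    if len(local_dataset) < local_dataset.k:
        raise ValueError("local RL dataset smaller than k")
    idx = knn_indices(local_dataset.states, np.asarray(features, dtype=float), local_dataset.k)
    actions = local_dataset.actions[idx]
    gains = local_dataset.gains()[idx]
    cands.sort(key=lambda dc: DIRECTION_ORDER.index(dc[0]))
    best, best_score = None, -math.inf
    for d, _ in cands:
        mask = actions == DIRECTION_ORDER.index(d)
        score = float(gains[mask].mean()) if mask.any() else -math.inf
        if score > best_score:
            best, best_score = d, score
    return best if best is not None else cands[0][0]
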