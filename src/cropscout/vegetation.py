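"""Excess-green vegetation index (ExG) and the 80%-of-field-mean health rule.

ExG on chromatic coordinates, ExG = 2*ghat - rhat - bhat with
rhat = R/(R+G+B) etc., is the crop-vigor proxy used to derive ground-truth
health labels: a zone is unhealthy iff its mean ExG falls below 80% of the
mean zone ExG of the field it belongs to (a zone exactly at the threshold is
healthy).
"""

from __future__ import annotations

import numpy as np

from .grid_core import HEALTHY, UNHEALTHY

#: Unhealthy iff zone ExG < HEALTH_THRESHOLD_FRACTION * field mean ExG.
HEALTH_THRESHOLD_FRACTION: float = 0.8


def exg_pixel(r: float, g: float, b: float, normalized: bool = True) -> float:
    """ExG of one pixel.

    With ``normalized`` (default) the channels are first converted to
    chromatic coordinates, giving a value in [-1, 2]; a black pixel
    (R+G+B = 0) returns 0 by convention.  With ``normalized=False`` the raw
    2G - R - B variant is returned (sensitivity checks only).
    """
    if r < 0 or g < 0 or b < 0:
        raise ValueError("channel values must be non-negative")
    if not normalized:
        return 2.0 * g - r - b
    s = r + g + b
    if s == 0:
        return 0.0
    return (2.0 * g - r - b) / s


def exg_image(tile: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Per-pixel ExG raster of an RGB tile (H, W, 3)."""
    tile = np.asarray(tile, dtype=float)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB tile")
    r, g, b = tile[..., 0], tile[..., 1], tile[..., 2]
    raw = 2.0 * g - r - b
    if not normalized:
        return raw
    s = r + g + b
    out = np.zeros_like(raw)
    np.divide(raw, s, out=out, where=s > 0)
    return out


def zone_exg(tile: np.ndarray, normalized: bool = True) -> float:
    """Mean ExG over all pixels of a zone tile."""
    tile = np.asarray(tile)
    if tile.size == 0:
        raise ValueError("empty tile")
    return float(np.mean(exg_image(tile, normalized=normalized)))


def field_zone_exg(zone_images: np.ndarray) -> np.ndarray:
    """Zone-mean ExG raster for a whole field's (rows, cols, H, W, 3) tiles."""
    tiles = np.asarray(zone_images, dtype=float)
    r = tiles[..., 0]
    g = tiles[..., 1]
    b = tiles[..., 2]
    s = r + g + b
    raw = 2.0 * g - r - b
    exg = np.zeros_like(raw)
    np.divide(raw, s, out=exg, where=s > 0)
    return exg.mean(axis=(-2, -1))


def label_field(zone_exg_values: np.ndarray | dict) -> np.ndarray | dict:
    """Health labels from zone-mean ExG via the 80%-of-field-mean rule.

    Accepts either a (rows, cols) array (returns an int8 label array) or a
    ``{coord: exg}`` mapping (returns a ``{coord: label}`` mapping).  The
    reference mean is taken over all zones of the given field.  Labels are
    scale-invariant: multiplying every ExG by c > 0 changes nothing.
    """
    if isinstance(zone_exg_values, dict):
        coords = list(zone_exg_values)
        arr = np.array([zone_exg_values[c] for c in coords], dtype=float)
        labels = _label_array(arr)
        return {c: int(l) for c, l in zip(coords, labels)}
    arr = np.asarray(zone_exg_values, dtype=float)
    return _label_array(arr).astype(np.int8)


def _label_array(arr: np.ndarray) -> np.ndarray:
    mean = float(np.mean(arr))
    if mean <= 0:
        raise ValueError(
            "field mean ExG is non-positive; the 80%-of-mean threshold rule is "
            "undefined (check imagery: a vegetated field has positive mean ExG)"
        )
    threshold = HEALTH_THRESHOLD_FRACTION * mean
    return np.where(arr < threshold, UNHEALTHY, HEALTHY)
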