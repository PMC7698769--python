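"""Field lattice, coordinate conventions, area partitioning and window extraction.

The field is a ``rows x cols`` lattice of management zones, addressed by
0-based ``(row, col)`` pairs in row-major order.  A scouting mission induces a
three-way partition of the zones:

* **visible** — zones the UAS has flown over (ground truth observed),
* **neighbor** — unobserved zones 8-adjacent to at least one visible zone,
* **unknown** — everything else.

A :class:`PredictionWindow` is the odd-sized, UAS-centered square sub-grid on
which extrapolation and RL state encoding operate.  Windows are clipped (not
padded) at field borders; out-of-bounds slots are marked and ignored by all
algorithms.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Health labels.  "Positive" means healthy everywhere in this codebase.
HEALTHY: int = 1
UNHEALTHY: int = 0

#: Default field-tile geometry: 1344 zones in a 42 x 32 grid of ~4.3 m2 zones.
DEFAULT_ROWS: int = 32
DEFAULT_COLS: int = 42
DEFAULT_ZONE_AREA_M2: float = 4.3

#: Window sizes the RL pipeline is exercised at.
WINDOW_SIZES: tuple[int, ...] = (7, 11, 15, 19, 23)


class Direction(enum.Enum):
    """The eight compass moves on the lattice, as ``(drow, dcol)`` deltas.

    North is decreasing row.  The enum order (N, NE, E, SE, S, SW, W, NW)
    is the fixed tie-break order used by the action-selection rules.
    """

    N = (-1, 0)
    NE = (-1, 1)
    E = (0, 1)
    SE = (1, 1)
    S = (1, 0)
    SW = (1, -1)
    W = (0, -1)
    NW = (-1, -1)

    @property
    def drow(self) -> int:
        return self.value[0]

    @property
    def dcol(self) -> int:
        return self.value[1]

    def apply(self, coord: tuple[int, int]) -> tuple[int, int]:
        return (coord[0] + self.drow, coord[1] + self.dcol)

    @classmethod
    def from_delta(cls, drow: int, dcol: int) -> "Direction":
        """Direction whose deltas are ``(sign(drow), sign(dcol))``.

        Any nonzero displacement maps onto one of the eight compass moves;
        used to attribute a direction to relocation flights.
        """
        dr, dc = int(np.sign(drow)), int(np.sign(dcol))
        if (dr, dc) == (0, 0):
            raise ValueError("zero displacement has no direction")
        return cls((dr, dc))


#: 4-connectivity subset, for the optional `flight_adjacency: 4` switch.
DIRECTIONS_4: tuple[Direction, ...] = (Direction.N, Direction.E, Direction.S, Direction.W)


class Status(enum.IntEnum):
    """Zone status inside an :class:`AreaPartition` or window raster."""

    OUT = -1  # outside the field (clipped window slots only)
    UNKNOWN = 0
    NEIGHBOR = 1
    VISIBLE = 2


def _check_bounds(coord: tuple[int, int], shape: tuple[int, int]) -> None:
    r, c = coord
    rows, cols = shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"coordinate {coord} out of bounds for grid {shape}")


def neighbors8(coord: tuple[int, int], grid_shape: tuple[int, int]) -> set[tuple[int, int]]:
    """All in-bounds 8-neighbors of ``coord``.

    Interior zones have 8, edges 5, corners 3.
    """
    _check_bounds(coord, grid_shape)
    r, c = coord
    rows, cols = grid_shape
    out = set()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                out.add((rr, cc))
    return out


def flight_neighbors(
    coord: tuple[int, int], grid_shape: tuple[int, int], adjacency: int = 8
) -> list[tuple[Direction, tuple[int, int]]]:
    """In-bounds flight moves from ``coord`` in fixed direction order.

    ``adjacency`` is 8 (default, consistent with the eight directional
    predictors) or 4 (rook moves only).
    """
    if adjacency not in (4, 8):
        raise ValueError("adjacency must be 4 or 8")
    dirs = Direction if adjacency == 8 else DIRECTIONS_4
    rows, cols = grid_shape
    out = []
    for d in dirs:
        rr, cc = d.apply(coord)
        if 0 <= rr < rows and 0 <= cc < cols:
            out.append((d, (rr, cc)))
    return out


@dataclass(frozen=True)
class AreaPartition:
    """Visible / neighbor / unknown status raster over a grid.

    The three sets are disjoint and cover the grid; every neighbor zone is
    8-adjacent to at least one visible zone, and no unknown zone is.
    """

    status: np.ndarray  # int8 array of Status values, shape (rows, cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.status.shape  # type: ignore[return-value]

    def zones(self, which: Status) -> set[tuple[int, int]]:
        rr, cc = np.nonzero(self.status == which)
        return set(zip(rr.tolist(), cc.tolist()))

    def counts(self) -> dict[str, int]:
        return {
            "visible": int(np.sum(self.status == Status.VISIBLE)),
            "neighbor": int(np.sum(self.status == Status.NEIGHBOR)),
            "unknown": int(np.sum(self.status == Status.UNKNOWN)),
        }


def partition(visited: Iterable[tuple[int, int]], grid_shape: tuple[int, int]) -> AreaPartition:
    """Partition the grid induced by a visited set.

    visible = visited; neighbor = zones 8-adjacent to a visible zone but not
    visible; unknown = the rest.
    """
    visited = set(visited)
    if not visited:
        raise ValueError("visited set is empty: no observation to extrapolate from")
    for coord in visited:
        _check_bounds(coord, grid_shape)
    status = np.zeros(grid_shape, dtype=np.int8)
    rr = np.array([c[0] for c in visited])
    cc = np.array([c[1] for c in visited])
    vis = np.zeros(grid_shape, dtype=bool)
    vis[rr, cc] = True
    # dilate the visible mask by one 8-connected ring
    padded = np.pad(vis, 1)
    near = np.zeros(grid_shape, dtype=bool)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            near |= padded[dr : dr + grid_shape[0], dc : dc + grid_shape[1]]
    status[near & ~vis] = Status.NEIGHBOR
    status[vis] = Status.VISIBLE
    return AreaPartition(status=status)


@dataclass
class FieldGrid:
    """The world: a lattice of management zones with tiles and/or truth labels.

    ``truth_labels`` is a (rows, cols) int array with values HEALTHY/UNHEALTHY,
    ``zone_images`` a (rows, cols, px, px, 3) uint8 array of per-zone RGB tiles.
    Either may be absent depending on the pipeline stage.
    """

    rows: int = DEFAULT_ROWS
    cols: int = DEFAULT_COLS
    zone_area_m2: float = DEFAULT_ZONE_AREA_M2
    truth_labels: np.ndarray | None = None
    zone_images: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.truth_labels is not None:
            self.truth_labels = np.asarray(self.truth_labels)
            if self.truth_labels.shape != self.shape:
                raise ValueError("truth_labels shape mismatch")
        if self.zone_images is not None and self.zone_images.shape[:2] != self.shape:
            raise ValueError("zone_images shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def n_zones(self) -> int:
        return self.rows * self.cols

    def border_zones(self) -> list[tuple[int, int]]:
        """Zones on the field edge, in row-major order (random-path starts)."""
        out = []
        for r in range(self.rows):
            for c in range(self.cols):
                if r in (0, self.rows - 1) or c in (0, self.cols - 1):
                    out.append((r, c))
        return out

    # -- manifest I/O ------------------------------------------------------

    def save(self, directory: str | Path, save_tiles: bool = True) -> None:
        """Write manifest JSON + labels CSV (+ PNG tiles) to a directory."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"rows": self.rows, "cols": self.cols, "zone_area_m2": self.zone_area_m2}
        if self.truth_labels is not None:
            rows_ = []
            for r in range(self.rows):
                for c in range(self.cols):
                    rows_.append((r, c, int(self.truth_labels[r, c])))
            pd.DataFrame(rows_, columns=["row", "col", "label"]).to_csv(
                directory / "labels.csv", index=False
            )
            manifest["labels_csv"] = "labels.csv"
        if save_tiles and self.zone_images is not None:
            tile_dir = directory / "tiles"
            tile_dir.mkdir(exist_ok=True)
            for r in range(self.rows):
                for c in range(self.cols):
                    Image.fromarray(self.zone_images[r, c]).save(tile_dir / f"zone_{r}_{c}.png")
            manifest["image_dir"] = "tiles"
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FieldGrid":
        from PIL import Image

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        rows, cols = manifest["rows"], manifest["cols"]
        labels = None
        if "labels_csv" in manifest:
            df = pd.read_csv(directory / manifest["labels_csv"])
            labels = np.zeros((rows, cols), dtype=np.int8)
            labels[df["row"].to_numpy(), df["col"].to_numpy()] = df["label"].to_numpy()
        images = None
        if "image_dir" in manifest:
            tile_dir = directory / manifest["image_dir"]
            first = np.asarray(Image.open(tile_dir / "zone_0_0.png"))
            images = np.zeros((rows, cols) + first.shape, dtype=np.uint8)
            for r in range(rows):
                for c in range(cols):
                    images[r, c] = np.asarray(Image.open(tile_dir / f"zone_{r}_{c}.png"))
        return cls(
            rows=rows,
            cols=cols,
            zone_area_m2=manifest.get("zone_area_m2", DEFAULT_ZONE_AREA_M2),
            truth_labels=labels,
            zone_images=images,
        )


@dataclass
class PredictionWindow:
    """UAS-centered ``w x w`` sub-grid: the unit of extrapolation and RL state.

    All per-zone rasters are full ``(w, w)`` arrays in window-local
    coordinates; slots that fall outside the field carry ``Status.OUT`` and
    NaN and are skipped by every algorithm.  ``tile_source`` identifies the
    image standing at each slot: ``("field", r, c)`` for an observed zone,
    ``("ref", i)`` for a substituted reference tile, or ``None``.
    """

    size: int
    center: tuple[int, int]
    grid_shape: tuple[int, int]
    status: np.ndarray  # (w, w) int8 of Status
    labels: np.ndarray  # (w, w) float: 1.0 healthy / 0.0 unhealthy / NaN
    probs: np.ndarray  # (w, w) float: P(healthy) or NaN
    truth_mask: np.ndarray  # (w, w) bool: slot holds originally-observed ground truth
    tile_source: list  # (w, w) nested list of tile refs

    @property
    def radius(self) -> int:
        return (self.size - 1) // 2

    @property
    def origin(self) -> tuple[int, int]:
        """Grid coordinate of window slot (0, 0) (may be out of bounds)."""
        return (self.center[0] - self.radius, self.center[1] - self.radius)

    def to_grid(self, wr: int, wc: int) -> tuple[int, int]:
        return (self.origin[0] + wr, self.origin[1] + wc)

    def to_window(self, r: int, c: int) -> tuple[int, int]:
        return (r - self.origin[0], c - self.origin[1])

    @property
    def in_bounds(self) -> np.ndarray:
        return self.status != Status.OUT

    def counts(self) -> dict[str, int]:
        return {
            "visible": int(np.sum(self.status == Status.VISIBLE)),
            "neighbor": int(np.sum(self.status == Status.NEIGHBOR)),
            "unknown": int(np.sum(self.status == Status.UNKNOWN)),
        }

    def is_fully_visible(self) -> bool:
        return bool(np.all((self.status == Status.VISIBLE) | (self.status == Status.OUT)))

    def copy(self) -> "PredictionWindow":
        return PredictionWindow(
            size=self.size,
            center=self.center,
            grid_shape=self.grid_shape,
            status=self.status.copy(),
            labels=self.labels.copy(),
            probs=self.probs.copy(),
            truth_mask=self.truth_mask.copy(),
            tile_source=[row[:] for row in self.tile_source],
        )

    def recompute_partition(self) -> None:
        """Re-derive NEIGHBOR/UNKNOWN statuses from the current visible set.

        Adjacency is evaluated within the window (the fill algorithm never
        reaches outside it).
        """
        w = self.size
        vis = self.status == Status.VISIBLE
        padded = np.pad(vis, 1)
        near = np.zeros((w, w), dtype=bool)
        for dr in (0, 1, 2):
            for dc in (0, 1, 2):
                near |= padded[dr : dr + w, dc : dc + w]
        inb = self.in_bounds
        self.status[inb & ~vis & near] = Status.NEIGHBOR
        self.status[inb & ~vis & ~near] = Status.UNKNOWN


def extract_window(
    grid: FieldGrid,
    part: AreaPartition,
    center: tuple[int, int],
    w: int,
) -> PredictionWindow:
    """Cut the ``w x w`` window centered on the current UAS position.

    The center must be visible; ``w`` must be odd.  Statuses, truth labels of
    visible zones and tile references are copied from the parent grid; the
    window is clipped at field borders (out-of-field slots are ``Status.OUT``).
    """
    if w % 2 == 0 or w < 1:
        raise ValueError(f"window size must be odd and positive, got {w}")
    _check_bounds(center, grid.shape)
    if part.status[center] != Status.VISIBLE:
        raise RuntimeError(f"window center {center} is not a visible zone")

    rad = (w - 1) // 2
    status = np.full((w, w), Status.OUT, dtype=np.int8)
    labels = np.full((w, w), np.nan)
    probs = np.full((w, w), np.nan)
    truth_mask = np.zeros((w, w), dtype=bool)
    tile_source: list = [[None] * w for _ in range(w)]

    r0, c0 = center[0] - rad, center[1] - rad
    for wr in range(w):
        for wc in range(w):
            r, c = r0 + wr, c0 + wc
            if not (0 <= r < grid.rows and 0 <= c < grid.cols):
                continue
            st = Status(part.status[r, c])
            status[wr, wc] = st
            if st == Status.VISIBLE:
                truth_mask[wr, wc] = True
                tile_source[wr][wc] = ("field", r, c)
                if grid.truth_labels is not None:
                    lab = float(grid.truth_labels[r, c])
                    labels[wr, wc] = lab
                    probs[wr, wc] = lab

    # Statuses are the full-grid partition restricted to the window.  A zone
    # can be NEIGHBOR here while having no visible neighbor inside the window
    # (its visible contact lies just outside); the fill algorithm recomputes a
    # window-local partition before predicting, since it never queries outside
    # the window.
    return PredictionWindow(
        size=w,
        center=center,
        grid_shape=grid.shape,
        status=status,
        labels=labels,
        probs=probs,
        truth_mask=truth_mask,
        tile_source=tile_source,
    )
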