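"""Eight directional spatial predictors, their ensemble, and the reference set.

For each of the eight compass directions ``d`` there is one predictor that
answers: *given the image of the observed zone sitting at offset ``d`` from
an unobserved target zone, is the target healthy?*  It is trained on pairs
(tile at ``center + d``, truth label at ``center``) over the interior zones
of the training fields, exploiting spatial autocorrelation of crop health.

A zone adjacent to several observed zones gets one prediction per visible
neighbor (each through that neighbor's direction-specific predictor); the
ensemble probability is their arithmetic mean.

The **reference set** holds held-out zone images scored once with a
prediction confidence (probability of healthy).  When the fill algorithm
predicts an unobserved zone, the reference image with the closest confidence
is substituted at that position so the zone can act as pseudo-observed input
in later iterations.

The default backend is a seeded logistic classifier over per-tile color and
ExG statistics; any object with ``fit_features``/``predict_features`` (or
``fit``/``predict`` on tiles) can stand in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .grid_core import Direction, FieldGrid, HEALTHY, PredictionWindow, Status
from .vegetation import exg_image

DIRECTION_ORDER: tuple[Direction, ...] = tuple(Direction)
DIR_INDEX: dict[Direction, int] = {d: i for i, d in enumerate(DIRECTION_ORDER)}

TILE_FEATURE_NAMES: tuple[str, ...] = (
    "exg_mean",
    "exg_p10",
    "exg_p50",
    "exg_p90",
    "exg_std",
    "r_mean",
    "g_mean",
    "b_mean",
)


def tile_features(tile: np.ndarray) -> np.ndarray:
    """Per-tile feature vector: ExG statistics plus channel means."""
    tile = np.asarray(tile, dtype=float)
    exg = exg_image(tile)
    return np.array(
        [
            exg.mean(),
            np.percentile(exg, 10),
            np.percentile(exg, 50),
            np.percentile(exg, 90),
            exg.std(),
            tile[..., 0].mean() / 255.0,
            tile[..., 1].mean() / 255.0,
            tile[..., 2].mean() / 255.0,
        ]
    )


def tile_features_batch(tiles) -> np.ndarray:
    return np.stack([tile_features(t) for t in tiles])


class LogisticTileBackend:
    """Logistic-regression predictor over tile features.

    Degenerate one-class training data is handled with a Laplace-smoothed
    constant probability, so an all-healthy field still yields a usable
    (confidently healthy) predictor.
    """

    def __init__(self, C: float = 1.0, seed: int = 0) -> None:
        self.C = C
        self.seed = seed
        self._model: LogisticRegression | None = None
        self._const: float | None = None
        self.trained = False

    def fit(self, pairs) -> "LogisticTileBackend":
        tiles, labels = zip(*pairs)
        return self.fit_features(tile_features_batch(tiles), np.asarray(labels))

    def fit_features(self, X: np.ndarray, y: np.ndarray) -> "LogisticTileBackend":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(X) == 0:
            raise ValueError("no training examples")
        if len(np.unique(y)) < 2:
            self._const = (np.sum(y == HEALTHY) + 1.0) / (len(y) + 2.0)
            self._model = None
        else:
            self._model = LogisticRegression(C=self.C, max_iter=1000, random_state=self.seed)
            self._model.fit(X, y)
            self._healthy_col = int(np.where(self._model.classes_ == HEALTHY)[0][0])
        self.trained = True
        return self

    def predict(self, tile: np.ndarray) -> float:
        return float(self.predict_features(tile_features(tile)[None, :])[0])

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("backend not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._model is None:
            return np.full(len(X), self._const)
        return self._model.predict_proba(X)[:, self._healthy_col]


class ConstantBackend:
    """Stub backend returning a fixed probability of healthy (tests/demos)."""

    def __init__(self, p: float) -> None:
        self.p = float(p)
        self.trained = True

    def fit(self, pairs):
        return self

    def fit_features(self, X, y):
        return self

    def predict(self, tile) -> float:
        return self.p

    def predict_features(self, X) -> np.ndarray:
        return np.full(len(np.atleast_2d(X)), self.p)


@dataclass
class DirectionalPredictor:
    """One direction's predictor: observed neighbor at ``direction`` relative
    to the unobserved target."""

    direction: Direction
    backend: object

    @property
    def trained(self) -> bool:
        return bool(getattr(self.backend, "trained", False))

    def prob_healthy(self, tile: np.ndarray) -> float:
        return float(self.backend.predict(tile))

    def predict(self, tile: np.ndarray) -> tuple[int, float]:
        """(label, confidence-in-that-label); confidence is in [0.5, 1]."""
        p = self.prob_healthy(tile)
        label = HEALTHY if p >= 0.5 else 1 - HEALTHY
        return label, max(p, 1.0 - p)


@dataclass
class DirectionalEnsemble:
    """The bundle of eight directional predictors."""

    predictors: dict[Direction, DirectionalPredictor] = field(default_factory=dict)

    def __getitem__(self, d: Direction) -> DirectionalPredictor:
        return self.predictors[d]

    @property
    def trained(self) -> bool:
        return len(self.predictors) == 8 and all(p.trained for p in self.predictors.values())

    def directional_probs(self, X_features: np.ndarray) -> np.ndarray:
        """(n, 8) probability-of-healthy, one column per Direction in order."""
        X_features = np.atleast_2d(X_features)
        cols = [
            self.predictors[d].backend.predict_features(X_features) for d in DIRECTION_ORDER
        ]
        return np.stack(cols, axis=1)

    def tile_score(self, X_features: np.ndarray) -> np.ndarray:
        """Direction-free confidence: mean of the eight backends on the tile
        itself (used to score reference images)."""
        return self.directional_probs(X_features).mean(axis=1)


def train_directional(
    train_fields: list[FieldGrid],
    backend_factory=None,
    seed: int = 0,
) -> DirectionalEnsemble:
    """Fit all eight directional predictors on labeled training fields.

    For direction ``d`` the training pairs are (tile at ``center + d``, truth
    label at ``center``) over all interior centers of every training field.
    """
    if not train_fields:
        raise ValueError("need at least one training field")
    for f in train_fields:
        if f.truth_labels is None or f.zone_images is None:
            raise ValueError("training fields need both truth labels and zone images")
    if backend_factory is None:
        backend_factory = lambda d_idx: LogisticTileBackend(seed=seed + d_idx)  # noqa: E731

    # features for every zone of every field, computed once
    feats = []
    for f in train_fields:
        F = np.stack(
            [
                np.stack([tile_features(f.zone_images[r, c]) for c in range(f.cols)])
                for r in range(f.rows)
            ]
        )
        feats.append(F)

    ensemble = DirectionalEnsemble()
    for di, d in enumerate(DIRECTION_ORDER):
        X, y = [], []
        for f, F in zip(train_fields, feats):
            rr = np.arange(1, f.rows - 1)
            cc = np.arange(1, f.cols - 1)
            for r in rr:
                for c in cc:
                    X.append(F[r + d.drow, c + d.dcol])
                    y.append(int(f.truth_labels[r, c]))
        backend = backend_factory(di)
        backend.fit_features(np.asarray(X), np.asarray(y))
        ensemble.predictors[d] = DirectionalPredictor(direction=d, backend=backend)
    return ensemble


# ---------------------------------------------------------------------------
# Reference set


@dataclass
class ReferenceSet:
    """Held-out zone images with ensemble-scored confidences.

    ``confidences[i]`` is the probability-of-healthy assigned to ``tiles[i]``;
    ``dir_probs[i, j]`` caches the j-th directional backend's probability on
    that tile (used when the tile is substituted into a window).
    """

    tiles: list
    confidences: np.ndarray
    dir_probs: np.ndarray

    def __post_init__(self) -> None:
        if len(self.tiles) == 0:
            raise ValueError("reference set is empty")
        if not np.all(np.isfinite(self.confidences)):
            raise ValueError("reference confidences must be finite")

    def __len__(self) -> int:
        return len(self.tiles)

    def nearest(self, confidence: float) -> int:
        """Index of the entry with the closest confidence (ties: lowest index)."""
        return int(np.argmin(np.abs(self.confidences - confidence)))


def build_reference(tiles, ensemble: DirectionalEnsemble) -> ReferenceSet:
    """Score held-out tiles with the trained ensemble.

    Each tile's confidence is the mean of all eight directional backends
    applied to the tile itself (symmetric, direction-free).
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("no reference tiles given")
    if not ensemble.trained:
        raise RuntimeError("ensemble must be trained before building a reference set")
    X = tile_features_batch(tiles)
    dir_probs = ensemble.directional_probs(X)
    return ReferenceSet(tiles=tiles, confidences=dir_probs.mean(axis=1), dir_probs=dir_probs)


def nearest_reference(ref: ReferenceSet, confidence: float) -> int:
    """Index of the reference entry minimizing |entry confidence - query|.

    Equidistant entries resolve to the lowest index (stable).
    """
    return ref.nearest(confidence)


# ---------------------------------------------------------------------------
# Field-bound model bundle and the ensemble prediction rule


class ScoutingModels:
    """Trained ensemble + reference set, bound to one field for fast lookup.

    Caches the eight directional probabilities for every zone tile of the
    attached field and for every reference tile, so window filling and
    mission loops reduce to table lookups.
    """

    def __init__(self, ensemble: DirectionalEnsemble, reference: ReferenceSet | None = None):
        self.ensemble = ensemble
        self.reference = reference
        self._field_probs: np.ndarray | None = None

    def attach_field(self, grid: FieldGrid) -> "ScoutingModels":
        if grid.zone_images is None:
            raise ValueError("field has no zone images to predict from")
        F = tile_features_batch(
            grid.zone_images.reshape((-1,) + grid.zone_images.shape[2:])
        )
        self._field_probs = self.ensemble.directional_probs(F).reshape(
            grid.rows, grid.cols, 8
        )
        return self

    def source_dir_prob(self, source, d: Direction) -> float:
        """P(healthy at target) from the tile standing at ``source``, queried
        through direction ``d``'s predictor."""
        di = DIR_INDEX[d]
        kind = source[0]
        if kind == "field":
            if self._field_probs is None:
                raise RuntimeError("no field attached; call attach_field first")
            return float(self._field_probs[source[1], source[2], di])
        if kind == "ref":
            if self.reference is None:
                raise RuntimeError("no reference set available")
            return float(self.reference.dir_probs[source[1], di])
        if kind == "tile":
            return self.ensemble.predictors[d].prob_healthy(source[1])
        raise ValueError(f"unknown tile source {source!r}")


def ensemble_predict(
    target: tuple[int, int], window: PredictionWindow, models: ScoutingModels
) -> tuple[int, float]:
    """Predict one unobserved window zone from its visible 8-neighbors.

    ``target`` is in window-local coordinates.  Each visible neighbor ``nb``
    at offset ``d`` (so ``nb = target + d``) contributes its direction-``d``
    predictor's probability; the ensemble probability is the arithmetic mean
    and the label is healthy iff it is >= 0.5.
    """
    w = window.size
    tr, tc = target
    probs = []
    for d in DIRECTION_ORDER:
        nr, nc = tr + d.drow, tc + d.dcol
        if not (0 <= nr < w and 0 <= nc < w):
            continue
        if window.status[nr, nc] != Status.VISIBLE:
            continue
        src = window.tile_source[nr][nc]
        if src is None:
            continue
        probs.append(models.source_dir_prob(src, d))
    if not probs:
        raise RuntimeError(
            f"target {target} has no visible 8-neighbor in the window; "
            "respect the area partition before predicting"
        )
    p = float(np.mean(probs))
    label = HEALTHY if p >= 0.5 else 1 - HEALTHY
    return label, p
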