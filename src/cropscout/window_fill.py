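"""Two-stage prediction-window fill.

Starting from the observed flight path inside a window, each iteration
predicts every zone of the current neighbor area from the pre-iteration
visible set (a synchronous wavefront), substitutes for each newly predicted
zone the reference image of closest confidence, promotes the batch to
visible, and recomputes the partition.  Iterations repeat until the window
has no unknown (or neighbor) area, i.e. every in-bounds zone carries a label,
a confidence and an image.

Originally observed zones are never overwritten.  With the UAS-centered
window the wavefront needs at most ``(w - 1) / 2`` iterations.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .grid_core import HEALTHY, PredictionWindow, Status
from .neighbor_models import ReferenceSet, ScoutingModels, ensemble_predict


def fill_iteration(
    window: PredictionWindow,
    models: ScoutingModels,
    ref: ReferenceSet,
    sequential: bool = False,
) -> PredictionWindow:
    """One wavefront step (returns a new window; the input is untouched).

    All zones currently in the neighbor area are predicted from the
    pre-iteration visible set, assigned reference tiles, then promoted to
    visible.  With ``sequential=True`` fills within the iteration feed each
    other in row-major order (order-dependent; for comparison only).
    """
    win = window.copy()
    targets = np.argwhere(win.status == Status.NEIGHBOR)
    if len(targets) == 0:
        if np.any(win.status == Status.UNKNOWN):
            raise AssertionError("unknown area with empty neighbor area violates partition")
        return win

    source = win if sequential else window  # predictions read pre-iteration state
    updates = []
    for tr, tc in targets:
        label, p = ensemble_predict((int(tr), int(tc)), source, models)
        updates.append((int(tr), int(tc), label, p))
        if sequential:
            _apply(win, int(tr), int(tc), label, p, ref)
    if not sequential:
        for tr, tc, label, p in updates:
            _apply(win, tr, tc, label, p, ref)
    win.recompute_partition()
    return win


def _apply(win: PredictionWindow, tr: int, tc: int, label: int, p: float, ref: ReferenceSet):
    win.labels[tr, tc] = float(label)
    win.probs[tr, tc] = p
    win.tile_source[tr][tc] = ("ref", ref.nearest(p))
    win.status[tr, tc] = Status.VISIBLE


def fill_window(
    window: PredictionWindow,
    models: ScoutingModels,
    ref: ReferenceSet,
    sequential: bool = False,
    trace_dir: str | Path | None = None,
) -> PredictionWindow:
    """Fill the whole window (pure function of the input window).

    Every in-bounds zone ends visible with a label and confidence;
    originally observed zones keep their ground truth.  ``trace_dir`` dumps a
    per-iteration CSV + PNG heatmap of the evolving label raster.
    """
    if not np.any(window.status == Status.VISIBLE):
        raise RuntimeError("window has no visible zone to extrapolate from")
    if ref is None or len(ref) == 0:
        raise RuntimeError("empty reference set")

    win = window.copy()
    # window-local adjacency: a zone whose only visible contact lies outside
    # the window is unreachable from inside it and must re-partition as unknown
    win.recompute_partition()
    if trace_dir is not None:
        trace_dir = Path(trace_dir)
        trace_dir.mkdir(parents=True, exist_ok=True)
        _snapshot(win, trace_dir, 0)

    max_iter = win.size + 1
    it = 0
    while not win.is_fully_visible():
        before = win.counts()
        win = fill_iteration(win, models, ref, sequential=sequential)
        it += 1
        after = win.counts()
        if after["unknown"] + after["neighbor"] >= before["unknown"] + before["neighbor"]:
            raise RuntimeError("fill made no progress; window state is inconsistent")
        if trace_dir is not None:
            _snapshot(win, trace_dir, it)
        if it > max_iter:
            raise RuntimeError("fill exceeded the wavefront iteration bound")
    return win


def window_accuracy(window: PredictionWindow, truth: np.ndarray) -> float:
    """Fraction of in-bounds window zones whose label matches the truth map."""
    w = window.size
    ok = 0
    tot = 0
    for wr in range(w):
        for wc in range(w):
            if window.status[wr, wc] == Status.OUT:
                continue
            lab = window.labels[wr, wc]
            if np.isnan(lab):
                continue
            r, c = window.to_grid(wr, wc)
            tot += 1
            ok += int(int(lab) == int(truth[r, c]))
    return ok / tot if tot else float("nan")


def _snapshot(win: PredictionWindow, trace_dir: Path, it: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    rows = []
    for wr in range(win.size):
        for wc in range(win.size):
            rows.append(
                (wr, wc, int(win.status[wr, wc]), win.labels[wr, wc], win.probs[wr, wc])
            )
    pd.DataFrame(rows, columns=["wrow", "wcol", "status", "label", "prob"]).to_csv(
        trace_dir / f"iter_{it:02d}.csv", index=False
    )
    img = np.where(np.isnan(win.probs), 0.5, win.probs)
    plt.imsave(trace_dir / f"iter_{it:02d}.png", img, cmap="RdYlGn", vmin=0, vmax=1)
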