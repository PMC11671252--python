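"""Spatially resolved (searchlight) decoding over 2x2-electrode ROIs.

Each region of interest is a contiguous 2x2 block of electrodes (stride 1,
never straddling arrays): an ``r x c`` array contributes ``(r-1)(c-1)``
ROIs, so the stock 8x16 + 8x8 layout has 105 + 49 = 154.  Features are raw
voltage samples of the four member channels over a fixed window
(endpoint-inclusive; the default [-0.1, 2.0] s at 500 Hz gives
4 x 1051 = 4204 features per trial).  Accuracy maps carry bootstrap
significance with FDR pooled across all ROIs of all arrays, plus a
per-array mask of ROIs at or above the 95th percentile of accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoding import DecodingResult, FeatureMatrix, bootstrap_significance, \
    decode_point, fdr_bh
from .epochs import TrialEpochs
from .grid import GridSet

__all__ = ["ROI", "SearchlightMap", "enumerate_rois", "roi_features",
           "searchlight_decode"]

DEFAULT_WINDOW = (-0.100, 2.000)


@dataclass(frozen=True)
class ROI:
    """A 2x2 searchlight block; (row, col) is its top-left electrode and the
    center sits between the four members."""

    array_id: str
    row: int
    col: int
    channels: tuple[int, int, int, int]

    @property
    def center(self) -> tuple[float, float]:
        return (self.row + 0.5, self.col + 0.5)


@dataclass
class SearchlightMap:
    """Per-ROI decoding results over one or more arrays."""

    rois: list[ROI]
    results: list[DecodingResult]
    grid: GridSet
    top_percentile_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    percentile: float = 95.0

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.results])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for roi, res, top in zip(self.rois, self.results,
                                 self.top_percentile_mask):
            rows.append({
                "array": roi.array_id, "roi_row": roi.row, "roi_col": roi.col,
                "accuracy": res.accuracy, "boot_median": res.boot_median,
                "ci_low": res.ci[0] if res.ci else np.nan,
                "ci_high": res.ci[1] if res.ci else np.nan,
                "p_raw": res.p_raw, "p_adjusted": res.p_adjusted,
                "top_percentile": bool(top),
            })
        return pd.DataFrame(rows)


def enumerate_rois(grid: GridSet) -> list[ROI]:
    """All contiguous 2x2 blocks of every array, stride 1, row-major order.

    Raises for any array smaller than 2x2.
    """
    grid = GridSet.coerce(grid)
    rois: list[ROI] = []
    for g in grid.grids:
        if g.rows < 2 or g.cols < 2:
            raise ValueError(
                f"array {g.array_id!r} ({g.rows}x{g.cols}) too small for 2x2 ROIs"
            )
        for r in range(g.rows - 1):
            for c in range(g.cols - 1):
                chans = tuple(grid.global_channel(g.array_id, rr, cc)
                              for rr in (r, r + 1) for cc in (c, c + 1))
                rois.append(ROI(g.array_id, r, c, chans))
    return rois


def roi_features(epochs: TrialEpochs, roi: ROI,
                 window: tuple[float, float] = DEFAULT_WINDOW) -> FeatureMatrix:
    """Concatenated raw voltages of the ROI's four channels over ``window``
    (endpoints included): ``n_trials x (4 * n_samples_in_window)``."""
    idx = epochs.time_indices(window, inclusive=True)
    if idx.size == 0 or window[0] < epochs.times[0] - 0.5 / epochs.fs \
            or window[1] > epochs.times[-1] + 0.5 / epochs.fs:
        raise ValueError(f"window {window} outside epoch "
                         f"[{epochs.times[0]}, {epochs.times[-1]}]")
    x = epochs.data[:, list(roi.channels), :][:, :, idx]
    x = x.reshape(epochs.n_trials, -1)
    return FeatureMatrix(x=x, y=epochs.labels.copy(),
                         provenance=f"roi {roi.array_id}({roi.row},{roi.col}) "
                                    f"window {window}")


def searchlight_decode(epochs: TrialEpochs, labels: np.ndarray | None = None,
                       grid: GridSet | None = None,
                       window: tuple[float, float] = DEFAULT_WINDOW,
                       n_folds: int = 5, n_boot: int = 0, q: float = 0.05,
                       percentile: float = 95.0,
                       seed: int | None = 0) -> SearchlightMap:
    """Decode category in every ROI and assemble the accuracy map.

    With ``n_boot > 0`` each ROI gets bootstrap CI and p, and FDR is applied
    jointly over the ROIs of *all* arrays.  The top-percentile mask is
    computed per array (linear interpolation between order statistics; ties
    at the threshold are included).
    """
    grid = GridSet.coerce(grid if grid is not None else epochs.grid)
    y = np.asarray(labels) if labels is not None else epochs.labels
    rois = enumerate_rois(grid)
    results: list[DecodingResult] = []
    for roi in rois:
        fm = roi_features(epochs, roi, window)
        res = decode_point(fm.x, y, n_folds=n_folds, seed=seed)
        if n_boot > 0:
            boot = bootstrap_significance(fm.x, y, n_boot=n_boot, seed=seed)
            res = DecodingResult(accuracy=res.accuracy,
                                 fold_accuracies=res.fold_accuracies,
                                 boot_median=boot.boot_median, ci=boot.ci,
                                 p_raw=boot.p_raw, n_boot=n_boot)
        results.append(res)

    if n_boot > 0:
        p = np.array([r.p_raw for r in results])
        reject, p_adj = fdr_bh(p, q=q)
        for r, pa in zip(results, p_adj):
            r.p_adjusted = float(pa)

    acc = np.array([r.accuracy for r in results])
    top = np.zeros(len(rois), dtype=bool)
    for g in grid.grids:
        members = np.array([i for i, roi in enumerate(rois)
                            if roi.array_id == g.array_id])
        thr = np.percentile(acc[members], percentile)
        top[members] = acc[members] >= thr
    return SearchlightMap(rois=rois, results=results, grid=grid,
                          top_percentile_mask=top, percentile=percentile)
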