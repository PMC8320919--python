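"""Characteristic curves: percentage of stained tissue versus saturation threshold.

The characteristic curve of a tile is p(t) = 100 * |stain(t)| / |ROI| sampled
on a fixed grid of saturation thresholds (default 0.10 to 0.50 in steps of
0.02, 21 points).  Because raising the threshold can only shrink the stain
mask, every curve is non-increasing; its height and drop-off rate track the
intensity and extent of membrane staining and hence the HER2 score: a
score-0 tile stays below 10% everywhere, a 3+ tile stays above 30%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .color_roi import RGBTile, EmptyROIError, rgb_to_hsv, roi_mask, stain_mask

__all__ = [
    "default_grid",
    "CharacteristicCurve",
    "compute_curve",
    "area_under_curve",
    "downsample_indices",
    "downsample_curve",
    "sampling_sweep",
    "curves_to_frame",
]


def default_grid(config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The saturation-threshold grid (strictly increasing, within [0, 1])."""
    g = config.grid.values()
    if g.ndim != 1 or len(g) < 2 or np.any(np.diff(g) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    if g[0] < 0 or g[-1] > 1:
        raise ValueError("threshold grid must lie within [0, 1]")
    return g


@dataclass(frozen=True)
class CharacteristicCurve:
    """Percentage-stained values ``p`` (each in [0, 100]) over threshold grid ``t``."""

    t: np.ndarray
    p: np.ndarray
    tile_id: str = "tile"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("t and p must be 1-D arrays of equal length")
        if np.any(p < -1e-9) or np.any(p > 100 + 1e-9):
            raise ValueError("curve values must lie in [0, 100]")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)

    def __len__(self) -> int:
        return len(self.t)


def compute_curve(tile: RGBTile, grid: np.ndarray | None = None,
                  config: PipelineConfig = DEFAULT_CONFIG) -> CharacteristicCurve:
    """Characteristic curve of a tile.

    Raises
    ------
    EmptyROIError
        If the tile contains no tissue pixels (never a silent 0/0).
    """
    if grid is None:
        grid = default_grid(config)
    hsv = rgb_to_hsv(tile)
    roi = roi_mask(hsv, config=config)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise EmptyROIError(f"no tissue in tile {tile.id!r}")
    p = np.empty(len(grid))
    for i, t in enumerate(grid):
        p[i] = 100.0 * stain_mask(hsv, roi, float(t), config=config).sum() / n_roi
    return CharacteristicCurve(t=np.asarray(grid, dtype=float), p=p, tile_id=tile.id)


def area_under_curve(curve: CharacteristicCurve) -> float:
    """Trapezoidal integral of p over the grid range (percent x saturation units)."""
    return float(np.trapezoid(curve.p, curve.t))


def downsample_indices(length: int, n_points: int) -> np.ndarray:
    """Index positions for curve downsampling.

    When exactly half the grid is requested (2 * n_points = length - 1, the
    default 10 of 21), every second grid point is taken starting at the
    first — the lowest, most informative threshold.  Any other size uses
    evenly spaced indices round(k*(L-1)/(n-1)), keeping both endpoints.
    """
    if not 2 <= n_points <= length:
        raise ValueError(f"n_points must lie in [2, {length}], got {n_points}")
    if 2 * n_points == length - 1:  # e.g. 10 of 21: indices 0, 2, ..., 18
        return np.arange(n_points) * 2
    k = np.arange(n_points)
    return np.round(k * (length - 1) / (n_points - 1)).astype(int)


def downsample_curve(curve: CharacteristicCurve, n_points: int = 10) -> np.ndarray:
    """Curve values at the evenly spaced index positions (default 10 of 21)."""
    return curve.p[downsample_indices(len(curve), n_points)]


def curves_to_frame(curves: Sequence[CharacteristicCurve]) -> pd.DataFrame:
    """Long-format table (tile_id, t, p) for CSV export and plotting."""
    return pd.DataFrame({
        "tile_id": np.repeat([c.tile_id for c in curves], [len(c) for c in curves]),
        "t": np.concatenate([c.t for c in curves]),
        "p": np.concatenate([c.p for c in curves]),
    })


def sampling_sweep(curves: Sequence[CharacteristicCurve], labels: Sequence[str],
                   n_points_list: Sequence[int], repeats: int = 200,
                   train_frac: float = 0.70, seed: int = 0) -> pd.DataFrame:
    """Classification accuracy as a function of curve sampling density.

    For each candidate number of points, trains a one-vs-all logistic
    regression on characteristic-curve features only, repeating a random
    stratified train/test split (default 70/30, 200 repeats) and reporting
    the mean and standard deviation of test accuracy.  Used to choose how
    many of the 21 curve points are worth keeping.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.multiclass import OneVsRestClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.model_selection import train_test_split

    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("sampling_sweep needs at least 2 classes")
    if len(curves) != len(y):
        raise ValueError("curves and labels must have equal length")
    full = np.stack([c.p for c in curves])
    length = full.shape[1]
    ss = np.random.SeedSequence(seed)
    split_seeds = ss.generate_state(repeats) % (2**31)

    rows = []
    for n_points in n_points_list:
        X = full[:, downsample_indices(length, int(n_points))]
        accs = np.empty(repeats)
        for r in range(repeats):
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=train_frac, stratify=y,
                random_state=int(split_seeds[r]))
            clf = make_pipeline(
                StandardScaler(),
                OneVsRestClassifier(LogisticRegression(max_iter=2000)))
            clf.fit(Xtr, ytr)
            accs[r] = (clf.predict(Xte) == yte).mean()
        rows.append({"n_points": int(n_points),
                     "mean_accuracy": accs.mean(),
                     "std_accuracy": accs.std(ddof=0),
                     "repeats": repeats})
    return pd.DataFrame(rows)
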