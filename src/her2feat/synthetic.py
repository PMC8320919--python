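"""Synthetic IHC-like tiles with class-controlled staining statistics.

Real HER2 tiles are not redistributable, so the pipeline is exercised on
procedurally generated tiles that reproduce the statistics the features
respond to, class by class: the fraction of tissue stained, the saturation
distribution of the stain (which sets where the characteristic curve
drops), the spatial correlation length of the stained region (which sets
connectedness), and the brown-vs-blue colour split (which shapes the b*
histogram).

A tile is built by thresholding a smoothed random field at the exact
quantile that yields the target stain fraction, so the achieved fraction
is pinned by construction.  Stained pixels get DAB-brown hues with
saturations drawn around a class-specific mean; the remaining tissue gets
a bluish low-saturation counterstain; a background fraction is painted
near-white.  Class defaults follow the clinical scoring semantics: a
score-0 tile's characteristic curve stays below 10% everywhere, a 3+
tile's stays above 30%, with 1+ and 2+ in between.

Generation is fully deterministic: each tile's random stream derives from
the master seed plus its (class, index) position.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import color as skcolor

from .color_roi import RGBTile
from .morphology import largest_component_size

__all__ = [
    "LABELS",
    "ClassParams",
    "DEFAULT_CLASS_PARAMS",
    "DEFAULT_TILE_SIZE",
    "curve_matches_class",
    "generate_tile",
    "generate_tiles",
    "generate_dataset",
]

LABELS = ("0", "1+", "2+", "3+")

# '+' is awkward in filenames; labels.csv keeps the clinical strings
_LABEL_SLUG = {"0": "0", "1+": "1p", "2+": "2p", "3+": "3p"}


@dataclass(frozen=True)
class ClassParams:
    """Generator parameters for one HER2 class.

    ``stain_frac`` is the fraction of tissue pixels stained (pinned exactly
    by quantile thresholding); ``sat_mean``/``sat_spread`` parameterise the
    clipped-normal saturation of stained pixels; ``connectivity_scale`` is
    the Gaussian correlation length of the stain field in pixels,
    controlling how contiguous the stained region is.
    """

    stain_frac: float
    sat_mean: float
    sat_spread: float
    connectivity_scale: float
    hue_center: float = 30.0     # degrees, DAB brown
    hue_spread: float = 7.0
    stain_val_mean: float = 0.55
    stain_val_spread: float = 0.05
    counter_hue: float = 240.0   # haematoxylin blue
    counter_sat: float = 0.25
    counter_val: float = 0.75
    background_frac: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.stain_frac <= 1.0:
            raise ValueError("stain_frac must lie in [0, 1]")
        if not 0.0 < self.sat_mean <= 1.0:
            raise ValueError("sat_mean must lie in (0, 1]")
        if self.connectivity_scale < 1:
            raise ValueError("connectivity_scale must be >= 1 pixel")
        if not 0.0 <= self.background_frac < 1.0:
            raise ValueError("background_frac must lie in [0, 1)")


# Class defaults encode the scoring semantics: staining fraction, intensity
# and contiguity all rise with score; 1+ exceeds the 10% line only near the
# lowest thresholds, 3+ clears 30% across the whole grid.
DEFAULT_CLASS_PARAMS: Mapping[str, ClassParams] = {
    "0":  ClassParams(stain_frac=0.05, sat_mean=0.20, sat_spread=0.05,
                      connectivity_scale=4.0),
    "1+": ClassParams(stain_frac=0.12, sat_mean=0.25, sat_spread=0.06,
                      connectivity_scale=6.0),
    "2+": ClassParams(stain_frac=0.30, sat_mean=0.50, sat_spread=0.10,
                      connectivity_scale=10.0),
    "3+": ClassParams(stain_frac=0.55, sat_mean=0.75, sat_spread=0.07,
                      connectivity_scale=16.0),
}

DEFAULT_TILE_SIZE = 256

_GRID = np.round(np.arange(0.10, 0.50 + 1e-9, 0.02), 2)


def curve_matches_class(label: str, p: np.ndarray, t: np.ndarray) -> bool:
    """Whether a characteristic curve obeys its class's scoring rule.

    score 0: entirely below the 10% line; 1+: above 10% only on an initial
    segment (back below 10% from t = 0.25 on); 2+: above 10% initially and
    spanning a wide range; 3+: entirely above the 30% line.
    """
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    if label == "0":
        return bool(np.all(p < 10.0))
    if label == "1+":
        return bool(p[0] > 10.0 and np.all(p[t >= 0.25] < 10.0))
    if label == "2+":
        return bool(p[0] > 10.0 and p.max() - p.min() > 10.0 and p.min() < 30.0)
    if label == "3+":
        return bool(np.all(p > 30.0))
    raise ValueError(f"unknown HER2 label: {label!r}")


def _smooth_field(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    noise = rng.uniform(size=(size, size))
    return ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")


def _build_tile(label: str, rng: np.random.Generator, params: ClassParams,
                size: int, tile_id: str) -> tuple[RGBTile, dict]:
    if size < 64:
        raise ValueError("tile size must be at least 64")
    if params.stain_frac > 1.0 - params.background_frac + 1e-12:
        # stain lives inside the ROI; it cannot outnumber the tissue pixels
        raise ValueError("infeasible stain_frac for the requested background fraction")
    # background (glass/lumen) forms a few large contiguous areas, so its
    # correlation length is a quarter of the tile side
    bg_field = _smooth_field(rng, size, scale=size / 4)
    bg = bg_field <= np.quantile(bg_field, params.background_frac)
    roi = ~bg
    field = _smooth_field(rng, size, scale=params.connectivity_scale)
    thr = np.quantile(field[roi], 1.0 - params.stain_frac)
    stain = roi & (field > thr)
    counter = roi & ~stain

    hue = np.empty((size, size))
    sat = np.empty((size, size))
    val = np.empty((size, size))
    n_stain = int(stain.sum())
    hue[stain] = np.mod(rng.normal(params.hue_center, params.hue_spread, n_stain), 360.0)
    sat[stain] = np.clip(rng.normal(params.sat_mean, params.sat_spread, n_stain), 0.0, 1.0)
    val[stain] = np.clip(rng.normal(params.stain_val_mean, params.stain_val_spread,
                                    n_stain), 0.05, 0.85)
    n_counter = int(counter.sum())
    hue[counter] = np.mod(rng.normal(params.counter_hue, 10.0, n_counter), 360.0)
    sat[counter] = np.clip(rng.normal(params.counter_sat, 0.04, n_counter), 0.10, 0.60)
    val[counter] = np.clip(rng.normal(params.counter_val, 0.05, n_counter), 0.30, 0.88)
    n_bg = int(bg.sum())
    hue[bg] = rng.uniform(0.0, 360.0, n_bg)
    sat[bg] = rng.uniform(0.0, 0.04, n_bg)
    val[bg] = rng.uniform(0.94, 1.0, n_bg)

    hsv = np.dstack([hue / 360.0, sat, val])
    rgb = np.round(skcolor.hsv2rgb(hsv) * 255.0).astype(np.uint8)
    tile = RGBTile(pixels=rgb, id=tile_id)

    # ground truth from the generator's own masks and sampled saturations,
    # independent of the segmentation pipeline
    n_roi = int(roi.sum())
    record: dict = {"tile_id": tile_id, "label": label, "roi_frac": n_roi / size ** 2}
    for t in _GRID:
        record[f"stain_frac_at_{t:.2f}"] = float((sat[stain] >= t).sum()) / n_roi
    record["largest_cc_frac"] = largest_component_size(stain & (sat >= _GRID[0]), 8) / n_roi
    return tile, record


def generate_tile(label: str, seed: int, params: ClassParams | None = None,
                  size: int = DEFAULT_TILE_SIZE,
                  tile_id: str | None = None) -> tuple[RGBTile, dict]:
    """Generate one tile plus its ground-truth record.

    The record holds the achieved stain fraction of the ROI at each default
    grid threshold (keys ``stain_frac_at_0.10`` ...) and the largest
    stained-component fraction at the lowest threshold.  Identical
    (label, seed, params, size) arguments give byte-identical tiles.
    """
    if label not in LABELS:
        raise ValueError(f"unknown HER2 label: {label!r}")
    if params is None:
        params = DEFAULT_CLASS_PARAMS[label]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    tid = tile_id if tile_id is not None else f"synth_{_LABEL_SLUG[label]}_s{seed}"
    return _build_tile(label, rng, params, size, tid)


def generate_tiles(n_per_class: int, seed: int,
                   params: Mapping[str, ClassParams] | None = None,
                   size: int = DEFAULT_TILE_SIZE,
                   labels: Sequence[str] = LABELS
                   ) -> tuple[list[RGBTile], list[str], pd.DataFrame]:
    """Generate a balanced in-memory dataset.

    Returns the tiles, their labels, and the ground-truth table.  Per-tile
    random streams derive from (master seed, class index, tile index), so
    the dataset is reproducible and individual tiles are decoupled.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = dict(DEFAULT_CLASS_PARAMS) if params is None else dict(params)
    tiles: list[RGBTile] = []
    ys: list[str] = []
    records = []
    for ci, label in enumerate(labels):
        for i in range(n_per_class):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(ci, i)))
            tid = f"synth_{_LABEL_SLUG[label]}_{i:04d}"
            tile, rec = _build_tile(label, rng, params[label], size, tid)
            tiles.append(tile)
            ys.append(label)
            records.append(rec)
    return tiles, ys, pd.DataFrame(records)


def generate_dataset(out_dir: str | Path, n_per_class: int = 200, seed: int = 1,
                     params: Mapping[str, ClassParams] | None = None,
                     size: int = DEFAULT_TILE_SIZE) -> pd.DataFrame:
    """Write a balanced tile dataset to disk: PNGs, labels.csv, truth.csv.

    Returns the labels table (tile_id, label).  File content depends only
    on (n_per_class, seed, params, size).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiles, ys, truth = generate_tiles(n_per_class, seed, params=params, size=size)
    for tile in tiles:
        Image.fromarray(tile.pixels).save(out_dir / f"{tile.id}.png")
    labels_df = pd.DataFrame({"tile_id": [t.id for t in tiles], "label": ys})
    labels_df.to_csv(out_dir / "labels.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False, float_format="%.9g")
    return labels_df
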