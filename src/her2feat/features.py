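"""Assembly of the 38-dimensional per-tile feature vector and feature tables.

The descriptor concatenates, in fixed column order: 10 characteristic-curve
values (percent stained at evenly spaced thresholds), 25 reduced ULBP
values (curves U0..U4 at 5 thresholds each), the connectedness percentage,
and the b*-histogram entropy and energy — 38 numbers per tile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig, DEFAULT_CONFIG
from .color_roi import RGBTile, EmptyROIError, filter_tiles
from .curves import compute_curve, area_under_curve, downsample_curve
from .ulbp import ulbp_curves, reduce_ulbp, linear_parameterize
from .morphology import connectedness
from .histogram_stats import bstar_histogram, entropy, energy

log = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureVector",
    "assemble_features",
    "extract_from_tiles",
    "extract_dataset",
    "write_features",
    "read_features",
]

FEATURE_COLUMNS: tuple[str, ...] = (
    tuple(f"cc_{i:02d}" for i in range(10))
    + tuple(f"ulbp_{i:02d}" for i in range(25))
    + ("conn", "entropy", "energy")
)

_DIAG_COLUMNS: tuple[str, ...] = (
    ("cc_area",)
    + tuple(f"ulbp_slope_{i}" for i in range(8))
    + tuple(f"ulbp_intercept_{i}" for i in range(8))
    + tuple(f"ulbp_full_{i:03d}" for i in range(168))
)


@dataclass(frozen=True)
class FeatureVector:
    """The reduced 38-component descriptor of one tile."""

    tile_id: str
    cc: np.ndarray       # (10,) percent values in [0, 100]
    ulbp: np.ndarray     # (25,) fractions in [0, 1]
    conn: float          # percent in [0, 100]
    entropy: float       # bits
    energy: float        # fraction
    label: str | None = None

    def __post_init__(self) -> None:
        cc = np.asarray(self.cc, dtype=float)
        ul = np.asarray(self.ulbp, dtype=float)
        if cc.shape != (10,):
            raise ValueError(f"expected 10 curve values, got {cc.shape}")
        if ul.shape != (25,):
            raise ValueError(f"expected 25 ULBP values, got {ul.shape}")
        object.__setattr__(self, "cc", cc)
        object.__setattr__(self, "ulbp", ul)

    def values(self) -> np.ndarray:
        """The 38 numeric components in FEATURE_COLUMNS order."""
        return np.concatenate(
            [self.cc, self.ulbp, [self.conn, self.entropy, self.energy]])

    def as_dict(self) -> dict:
        d: dict = {"tile_id": self.tile_id, "label": self.label}
        d.update(zip(FEATURE_COLUMNS, self.values()))
        return d


def assemble_features(tile: RGBTile, config: PipelineConfig = DEFAULT_CONFIG,
                      label: str | None = None) -> FeatureVector:
    """Compute the full 38-component descriptor for one tile.

    Raises :class:`EmptyROIError` (with the tile id attached) for tiles
    without tissue; such tiles should have been removed by
    :func:`her2feat.color_roi.filter_tiles`.
    """
    try:
        curve = compute_curve(tile, config=config)
        cset = ulbp_curves(tile, config=config)
        conn = connectedness(tile, config=config)
    except EmptyROIError as exc:
        raise EmptyROIError(f"{exc} (tile_id={tile.id!r})") from None
    hist = bstar_histogram(tile)
    return FeatureVector(
        tile_id=tile.id,
        cc=downsample_curve(curve, config.curve.n_points),
        ulbp=reduce_ulbp(cset),
        conn=conn,
        entropy=entropy(hist),
        energy=energy(hist),
        label=label,
    )


def _diagnostics_row(tile: RGBTile, config: PipelineConfig) -> dict:
    curve = compute_curve(tile, config=config)
    cset = ulbp_curves(tile, config=config)
    row: dict = {"cc_area": area_under_curve(curve)}
    for i in range(8):
        fit = linear_parameterize(cset.curves[i], cset.t)
        row[f"ulbp_slope_{i}"] = fit.slope
        row[f"ulbp_intercept_{i}"] = fit.intercept
    row.update(zip((f"ulbp_full_{i:03d}" for i in range(168)),
                   cset.curves.ravel()))
    return row


def extract_from_tiles(tiles: Sequence[RGBTile],
                       labels: Sequence[str] | None = None,
                       config: PipelineConfig = DEFAULT_CONFIG,
                       apply_filter: bool = True,
                       diagnostics: bool = False) -> pd.DataFrame:
    """Feature table for an in-memory tile collection.

    Applies the minimum-ROI tile filter, assembles one row per surviving
    tile, and returns a DataFrame sorted by tile_id with columns
    ``tile_id, label, cc_00..cc_09, ulbp_00..ulbp_24, conn, entropy,
    energy`` (plus area, line-fit and full-ULBP columns when
    ``diagnostics`` is set).
    """
    label_of = {}
    if labels is not None:
        if len(labels) != len(tiles):
            raise ValueError("labels and tiles must have equal length")
        label_of = {t.id: y for t, y in zip(tiles, labels)}
    kept = filter_tiles(tiles, config=config) if apply_filter else list(tiles)
    log.info("extract: %d of %d tiles kept", len(kept), len(tiles))
    rows = []
    for tile in kept:
        fv = assemble_features(tile, config=config, label=label_of.get(tile.id))
        row = fv.as_dict()
        if diagnostics:
            row.update(_diagnostics_row(tile, config))
        rows.append(row)
    columns = ["tile_id", "label", *FEATURE_COLUMNS]
    if diagnostics:
        columns += list(_DIAG_COLUMNS)
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values("tile_id", kind="stable").reset_index(drop=True)


def extract_dataset(tile_dir: str | Path, labels_csv: str | Path | None = None,
                    config: PipelineConfig = DEFAULT_CONFIG,
                    diagnostics: bool = False) -> pd.DataFrame:
    """Feature table for a directory of PNG/TIFF tiles.

    Unreadable files are logged and skipped; a labels CSV (columns
    tile_id, label) must cover every readable tile or an error is raised.
    An empty directory yields an empty table with the full header.
    """
    tile_dir = Path(tile_dir)
    paths = sorted(p for p in tile_dir.iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff"})
    tiles: list[RGBTile] = []
    n_bad = 0
    for p in paths:
        try:
            tiles.append(RGBTile.from_file(p))
        except Exception as exc:  # noqa: BLE001 - we report and continue
            n_bad += 1
            log.error("skipping unreadable tile %s: %s", p.name, exc)
    if n_bad:
        log.warning("extract: skipped %d unreadable file(s)", n_bad)
    if not tiles:
        log.warning("extract: no readable tiles in %s", tile_dir)
    labels = None
    if labels_csv is not None:
        table = pd.read_csv(labels_csv, dtype=str)
        mapping = dict(zip(table["tile_id"], table["label"]))
        missing = [t.id for t in tiles if t.id not in mapping]
        if missing:
            raise ValueError(f"labels missing for tiles: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        labels = [mapping[t.id] for t in tiles]
    return extract_from_tiles(tiles, labels=labels, config=config,
                              diagnostics=diagnostics)


def write_features(df: pd.DataFrame, path: str | Path,
                   config: PipelineConfig = DEFAULT_CONFIG,
                   seed: int | None = None) -> None:
    """Write a feature CSV with a provenance comment line (config hash, seed)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# her2feat features config_hash={config.hash()} seed={seed}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def read_features(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV written by :func:`write_features`."""
    df = pd.read_csv(path, comment="#", dtype={"tile_id": str, "label": str})
    return df
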