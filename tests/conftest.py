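"""Shared fixtures: synthetic tiles and the default evaluation dataset."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from skimage import color as skcolor

from her2feat import (
    RGBTile,
    area_under_curve,
    bstar_histogram,
    compute_curve,
    connectedness,
    downsample_curve,
    energy,
    entropy,
    generate_tiles,
    reduce_ulbp,
    ulbp_curves,
)
from her2feat.features import FEATURE_COLUMNS


def hsv_tile(h_deg: float, s: float, v: float, shape=(16, 16), tile_id="uniform") -> RGBTile:
    """Uniform tile built from HSV (quantized to uint8 like real data)."""
    hsv = np.broadcast_to([h_deg / 360.0, s, v], (*shape, 3))
    rgb = np.round(skcolor.hsv2rgb(hsv) * 255.0).astype(np.uint8)
    return RGBTile(pixels=rgb, id=tile_id)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic evaluation dataset: 200 tiles per class, seed 1.

    Computes every feature family once per tile and returns both the
    per-tile measurement table and the 38-column feature table.
    """
    tiles, labels, truth = generate_tiles(n_per_class=200, seed=1)
    meas_rows = []
    feat_rows = []
    for tile, label in zip(tiles, labels):
        curve = compute_curve(tile)
        cset = ulbp_curves(tile)
        hist = bstar_histogram(tile)
        conn = connectedness(tile)
        meas_rows.append({
            "tile_id": tile.id,
            "label": label,
            "auc": area_under_curve(curve),
            "conn": conn,
            "entropy": entropy(hist),
            "energy": energy(hist),
            "curve_min": curve.p.min(),
            "curve_max": curve.p.max(),
        })
        vec = np.concatenate([
            downsample_curve(curve, 10),
            reduce_ulbp(cset),
            [conn, entropy(hist), energy(hist)],
        ])
        feat_rows.append({"tile_id": tile.id, "label": label,
                          **dict(zip(FEATURE_COLUMNS, vec))})
    return {
        "measurements": pd.DataFrame(meas_rows),
        "features": pd.DataFrame(feat_rows),
        "truth": truth,
    }
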