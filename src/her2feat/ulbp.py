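"""Rotation-invariant uniform local binary patterns over saturation thresholds.

A local binary pattern (LBP) encodes each interior pixel by comparing its 8
radius-1 neighbours to the centre (``>=`` so ties count as 1), yielding an
8-bit code.  A pattern is *uniform* if its circular sequence of bits has at
most two 0-to-1 transitions; grouping uniform patterns by their number of
set bits gives the nine rotation-invariant components U0..U8, with the
remaining patterns pooled in a non-uniform bin.  Here the texture substrate
is the binary stain mask at each saturation threshold (configurable to the
masked saturation channel), so as the threshold grows past the strongest
staining the mask empties, constant neighbourhoods dominate, and U0..U7 all
decay to zero while U8 — which mostly reflects featureless regions and is
discarded — absorbs the mass.  Sampling U0..U7 on the 21-threshold grid
gives eight 21-point feature curves (168 values), later reduced to the
25-value descriptor used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .color_roi import RGBTile, EmptyROIError, rgb_to_hsv, roi_mask, stain_mask
from .curves import default_grid, downsample_indices

__all__ = [
    "ULBPHistogram",
    "ULBPCurveSet",
    "LineFit",
    "ulbp_histogram",
    "ulbp_curves",
    "linear_parameterize",
    "pairwise_curve_similarity",
    "reduce_ulbp",
    "REDUCED_CURVES",
    "REDUCED_POINT_INDICES",
]

# 8-neighbour ring at radius 1, in circular order (no interpolation)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]

# the reduced descriptor keeps curves U0..U4 at 5 of the 21 grid points
REDUCED_CURVES = (0, 1, 2, 3, 4)
REDUCED_POINT_INDICES = (0, 5, 10, 15, 20)


def _build_lut() -> np.ndarray:
    """Map each 8-bit code to its histogram bin: 0..8 for uniform, 9 otherwise."""
    lut = np.empty(256, dtype=np.intp)
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        lut[code] = sum(bits) if transitions <= 2 else 9
    return lut


_LUT = _build_lut()


@dataclass(frozen=True)
class ULBPHistogram:
    """Fractions U0..U8 plus the pooled non-uniform bin.

    ``n_evaluated`` counts the interior ROI pixels scanned; when it is zero
    the histogram is all-zero and flagged ``empty``.
    """

    u: np.ndarray  # shape (9,)
    nonuniform: float
    n_evaluated: int

    @property
    def empty(self) -> bool:
        return self.n_evaluated == 0


def ulbp_histogram(values: np.ndarray, roi: np.ndarray) -> ULBPHistogram:
    """ULBP histogram of ``values`` over interior pixels of ``roi``.

    ``values`` may be a binary mask or any scalar image; neighbour bits are
    ``neighbour >= centre``.  Border pixels are never centres; a centre
    must lie inside the ROI but its neighbours need not.
    """
    values = np.asarray(values)
    roi = np.asarray(roi, dtype=bool)
    if values.shape != roi.shape or values.ndim != 2:
        raise ValueError("values and roi must be 2-D arrays of the same shape")
    if values.shape[0] < 3 or values.shape[1] < 3:
        raise ValueError("ULBP needs at least a 3 x 3 image")
    v = values.astype(np.float64, copy=False)
    centre = v[1:-1, 1:-1]
    codes = np.zeros(centre.shape, dtype=np.uint8)
    for k, (dy, dx) in enumerate(_OFFSETS):
        nb = v[1 + dy:v.shape[0] - 1 + dy, 1 + dx:v.shape[1] - 1 + dx]
        codes |= (nb >= centre).astype(np.uint8) << k
    inside = roi[1:-1, 1:-1]
    n = int(inside.sum())
    if n == 0:
        return ULBPHistogram(u=np.zeros(9), nonuniform=0.0, n_evaluated=0)
    counts = np.bincount(_LUT[codes[inside]], minlength=10)
    frac = counts / n
    return ULBPHistogram(u=frac[:9], nonuniform=float(frac[9]), n_evaluated=n)


@dataclass(frozen=True)
class ULBPCurveSet:
    """The 8 retained component curves U0..U7, each sampled on the threshold grid."""

    t: np.ndarray       # shape (L,)
    curves: np.ndarray  # shape (8, L), values in [0, 1]
    tile_id: str = "tile"

    def __post_init__(self) -> None:
        c = np.asarray(self.curves, dtype=float)
        t = np.asarray(self.t, dtype=float)
        if c.shape != (8, len(t)):
            raise ValueError(f"expected curves of shape (8, {len(t)}), got {c.shape}")
        if np.any(c < -1e-9) or np.any(c > 1 + 1e-9):
            raise ValueError("ULBP curve values must lie in [0, 1]")
        object.__setattr__(self, "curves", c)
        object.__setattr__(self, "t", t)


def ulbp_curves(tile: RGBTile, grid: np.ndarray | None = None,
                config: PipelineConfig = DEFAULT_CONFIG) -> ULBPCurveSet:
    """Compute the stain mask at each grid threshold and collect U0..U7 curves."""
    if grid is None:
        grid = default_grid(config)
    hsv = rgb_to_hsv(tile)
    roi = roi_mask(hsv, config=config)
    if not roi.any():
        raise EmptyROIError(f"no tissue in tile {tile.id!r}")
    substrate = config.ulbp.substrate
    out = np.empty((8, len(grid)))
    for i, t in enumerate(grid):
        mask = stain_mask(hsv, roi, float(t), config=config)
        if substrate == "mask":
            values = mask.astype(np.float64)
        elif substrate == "saturation":
            values = np.where(mask, hsv.saturation, 0.0)
        else:
            raise ValueError(f"unknown ULBP substrate: {substrate!r}")
        out[:, i] = ulbp_histogram(values, roi).u[:8]
    return ULBPCurveSet(t=np.asarray(grid, dtype=float), curves=out, tile_id=tile.id)


@dataclass(frozen=True)
class LineFit:
    """First-order approximation of a feature curve: slope per unit saturation
    and the value the fitted line takes at t = 0 (y-intercept)."""

    slope: float
    intercept: float


def linear_parameterize(curve: np.ndarray, t: np.ndarray) -> LineFit:
    """Ordinary least-squares line fit of curve values against threshold."""
    curve = np.asarray(curve, dtype=float)
    t = np.asarray(t, dtype=float)
    if curve.shape != t.shape or len(curve) < 2:
        raise ValueError("curve and t must be equal-length with at least 2 points")
    slope, intercept = np.polyfit(t, curve, 1)
    return LineFit(slope=float(slope), intercept=float(intercept))


def pairwise_curve_similarity(curvesets: Sequence[ULBPCurveSet],
                              threshold: float = 0.95
                              ) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Mean Pearson correlation between component curves across a dataset.

    For each pair (i, j) the Pearson correlation between curves U_i and U_j
    is averaged over samples; samples where either curve is constant are
    skipped for that pair (correlation undefined).  A pair whose mean
    similarity reaches ``threshold`` is reported as redundant.  Entries
    with no valid sample are NaN, never silently 0.

    Returns
    -------
    (matrix, redundant) : 8 x 8 symmetric matrix with unit diagonal, and
        the list of index pairs (i < j) with similarity >= threshold.
    """
    if len(curvesets) < 2:
        raise ValueError("pairwise similarity needs at least 2 samples")
    sums = np.zeros((8, 8))
    counts = np.zeros((8, 8), dtype=int)
    for cs in curvesets:
        c = cs.curves
        sd = c.std(axis=1)
        ok = sd > 1e-12  # constant curves (up to float roundoff) are skipped
        if not ok.any():
            continue
        z = np.zeros_like(c)
        z[ok] = (c[ok] - c[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        corr = z @ z.T / c.shape[1]
        valid = np.outer(ok, ok)
        sums[valid] += corr[valid]
        counts[valid] += 1
    with np.errstate(invalid="ignore"):
        matrix = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(matrix, 1.0)
    redundant = [(i, j) for i in range(8) for j in range(i + 1, 8)
                 if np.isfinite(matrix[i, j]) and matrix[i, j] >= threshold]
    return matrix, redundant


def reduce_ulbp(curveset: ULBPCurveSet) -> np.ndarray:
    """The 25-value reduced ULBP descriptor.

    Keeps curves U0..U4 only — the similarity analysis shows the higher
    components largely duplicate them — and samples each retained curve at
    5 of the 21 grid points (indices 0, 5, 10, 15, 20), exploiting the low
    curvature of the curves.  Output is curve-major: 5 values of U0, then
    U1, and so on.
    """
    if curveset.curves.shape[1] != 21:
        raise ValueError("reduce_ulbp expects the full 21-point threshold grid")
    idx = np.asarray(REDUCED_POINT_INDICES)
    return curveset.curves[np.asarray(REDUCED_CURVES)][:, idx].ravel()
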