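"""First-order statistics of the CIE-Lab b* channel histogram.

The colours of interest in a HER2 IHC tile fall along the blue-yellow axis:
haematoxylin counterstain is blue (negative b*), DAB staining brown/yellow
(positive b*), background near zero.  The tile is converted to CIE-Lab, b*
is mapped to a 256-level grey image by an affine shift of +128 with
clamping, and the normalised histogram's entropy (-sum p log2 p, bits) and
energy (sum p^2) summarise how spread out the colour distribution is.
Heavier staining widens the b* distribution, so entropy rises and energy
falls with HER2 score, and the two are inversely correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color_roi import RGBTile, rgb_to_lab

__all__ = ["GreyHistogram", "bstar_grey", "bstar_histogram", "entropy", "energy"]


@dataclass(frozen=True)
class GreyHistogram:
    """Normalised 256-bin grey-level histogram."""

    bins: np.ndarray  # shape (256,), fractions summing to 1
    n_pixels: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (256,):
            raise ValueError("histogram must have 256 bins")
        if np.any(b < 0):
            raise ValueError("histogram fractions must be non-negative")
        if self.n_pixels > 0 and abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("histogram fractions must sum to 1")
        object.__setattr__(self, "bins", b)


def bstar_grey(tile: RGBTile) -> np.ndarray:
    """Grey-level image of the b* channel: g = clamp(round(b* + 128), 0, 255)."""
    b = rgb_to_lab(tile).b
    return np.clip(np.round(b + 128.0), 0, 255).astype(np.uint8)


def bstar_histogram(tile: RGBTile) -> GreyHistogram:
    """Normalised 256-bin histogram of the b* grey image over the whole tile."""
    g = bstar_grey(tile)
    counts = np.bincount(g.ravel(), minlength=256)
    return GreyHistogram(bins=counts / g.size, n_pixels=int(g.size))


def entropy(hist: GreyHistogram) -> float:
    """Shannon entropy in bits, with 0 * log 0 := 0.  Ranges over [0, 8]."""
    p = hist.bins[hist.bins > 0]
    return float(-(p * np.log2(p)).sum())


def energy(hist: GreyHistogram) -> float:
    """Sum of squared bin fractions.  Ranges over [1/256, 1]."""
    return float((hist.bins ** 2).sum())
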