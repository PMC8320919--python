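"""Colour-space conversion and pixel classification for IHC tiles.

In immunohistochemistry slides stained for HER2, the DAB chromogen marks
positive membranes brown while the haematoxylin counterstain colours the
remaining tissue blue; the slide glass shows as near-white.  All stain
segmentation here works in HSV space: the region of interest (ROI) is the
set of tissue (non-background) pixels, and a pixel is "stained" if it lies
in the ROI, its hue falls in the brown band, and its saturation reaches
a threshold ``t``.  Raising ``t`` can only shrink the stain mask, which is
the nesting property the curve features build on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from skimage import color as skcolor

from .config import PipelineConfig, DEFAULT_CONFIG

log = logging.getLogger(__name__)

__all__ = [
    "EmptyROIError",
    "RGBTile",
    "HSVImage",
    "LabImage",
    "rgb_to_hsv",
    "rgb_to_lab",
    "roi_mask",
    "stain_mask",
    "roi_fraction",
    "filter_tiles",
]


class EmptyROIError(ValueError):
    """Raised when an operation requires tissue pixels but the tile has none."""


@dataclass(frozen=True)
class RGBTile:
    """An 8-bit RGB image patch, the unit of all feature computation.

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3), dtype uint8
        Row-major, origin top-left.
    id : str
        Tile identifier (file stem for tiles read from disk).
    """

    pixels: np.ndarray
    id: str = "tile"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"tile {self.id!r}: expected (H, W, 3) array, got {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(f"tile {self.id!r}: tiles must be at least 3 x 3")
        if px.dtype != np.uint8:
            raise ValueError(f"tile {self.id!r}: expected uint8 pixels, got {px.dtype}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_file(cls, path: str | Path) -> "RGBTile":
        """Read a PNG or TIFF tile; an alpha channel is dropped with a warning."""
        path = Path(path)
        img = Image.open(path)
        if img.mode in ("RGBA", "LA", "PA"):
            log.warning("tile %s has an alpha channel; dropping it", path.name)
            img = img.convert("RGB")
        elif img.mode != "RGB":
            img = img.convert("RGB")
        return cls(pixels=np.asarray(img, dtype=np.uint8), id=path.stem)


@dataclass(frozen=True)
class HSVImage:
    """Per-pixel hue (degrees in [0, 360)), saturation and value in [0, 1].

    Hue of achromatic pixels is defined as 0.
    """

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray


@dataclass(frozen=True)
class LabImage:
    """Per-pixel CIE-Lab: L in [0, 100], signed a* (green-red) and b* (blue-yellow)."""

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray


def rgb_to_hsv(tile: RGBTile) -> HSVImage:
    """Standard per-pixel RGB -> HSV conversion (S = 0 where R = G = B)."""
    hsv = skcolor.rgb2hsv(tile.pixels)
    return HSVImage(hue=hsv[..., 0] * 360.0, saturation=hsv[..., 1], value=hsv[..., 2])


def rgb_to_lab(tile: RGBTile) -> LabImage:
    """Per-pixel sRGB -> CIE-Lab conversion (D65 white point)."""
    lab = skcolor.rgb2lab(tile.pixels)
    return LabImage(L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def roi_mask(hsv: HSVImage, bg_sat_max: float | None = None,
             bg_val_min: float | None = None,
             config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Boolean tissue mask: background iff S < bg_sat_max AND V > bg_val_min.

    Slide background is near-white (bright and nearly achromatic); both
    counterstained and DAB-stained tissue are chromatic or darker, so the
    ROI is the complement of that background test.
    """
    bg_sat_max = config.roi.bg_sat_max if bg_sat_max is None else bg_sat_max
    bg_val_min = config.roi.bg_val_min if bg_val_min is None else bg_val_min
    if not (0.0 <= bg_sat_max <= 1.0 and 0.0 <= bg_val_min <= 1.0):
        raise ValueError("ROI thresholds must lie in [0, 1]")
    background = (hsv.saturation < bg_sat_max) & (hsv.value > bg_val_min)
    return ~background


def _hue_in_band(hue: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # bands may wrap across 0 degrees; membership is tested modulo 360
    lo, hi = lo % 360.0, hi % 360.0
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    return (hue >= lo) | (hue <= hi)


def stain_mask(hsv: HSVImage, roi: np.ndarray, t: float,
               hue_band: tuple[float, float] | None = None,
               val_max: float | None = None,
               config: PipelineConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Boolean DAB mask at saturation threshold ``t``.

    A pixel is stained iff it lies in ``roi``, its hue is in the brown
    band, its value is at most ``val_max`` (glare exclusion) and S >= t.
    The comparison is inclusive, so ``stain_mask(t2) <= stain_mask(t1)``
    exactly whenever ``t2 >= t1``.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"saturation threshold must lie in [0, 1], got {t}")
    if hue_band is None:
        hue_band = (config.stain.hue_low_deg, config.stain.hue_high_deg)
    if val_max is None:
        val_max = config.stain.val_max
    return (
        roi
        & _hue_in_band(hsv.hue, *hue_band)
        & (hsv.value <= val_max)
        & (hsv.saturation >= t)
    )


def roi_fraction(tile: RGBTile, config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """Fraction of tile pixels classified as tissue."""
    roi = roi_mask(rgb_to_hsv(tile), config=config)
    return float(roi.mean())


def filter_tiles(tiles: Sequence[RGBTile], min_roi_frac: float | None = None,
                 config: PipelineConfig = DEFAULT_CONFIG) -> list[RGBTile]:
    """Drop tiles whose tissue fraction falls below ``min_roi_frac``.

    Mirrors the whole-slide tiling step that removes patches containing
    mostly glass.  Order is preserved; the boundary is kept (``>=``).
    """
    min_roi_frac = config.tiles.min_roi_frac if min_roi_frac is None else min_roi_frac
    if not 0.0 <= min_roi_frac <= 1.0:
        raise ValueError("min_roi_frac must lie in [0, 1]")
    kept = [t for t in tiles if roi_fraction(t, config=config) >= min_roi_frac]
    log.info("filter_tiles: kept %d of %d tiles (min_roi_frac=%.2f)",
             len(kept), len(tiles), min_roi_frac)
    return kept
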