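"""Leaf segmentation: spectral-index masks, mask I/O and resolution transfer.

Featurization must be restricted to plant tissue.  Masks can come from three
sources: a normalized-difference vegetation index threshold on the calibrated
VNIR cube (the built-in method), an external segmentation tool (masks are
read from 8-bit image files), or the synthetic generator's ground truth.
Because the VNIR camera has the higher spatial resolution, masks are computed
there and downscaled to SWIR dimensions by area-weighted block averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .hsi_io import SpectralCube, nearest_band

__all__ = ["LeafMask", "segment_by_index", "mask_iou", "downscale_mask",
           "read_mask", "write_mask"]


@dataclass
class LeafMask:
    """Binary foreground map aligned to one cube."""

    values: np.ndarray
    source: str = "index"  # index | external | truth

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def leaf_fraction(self) -> float:
        return float(self.values.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def segment_by_index(cube: SpectralCube, red_nm: float = 680.0,
                     nir_nm: float = 780.0, threshold: float = 0.3,
                     min_object_px: int = 64) -> LeafMask:
    """Threshold the normalized-difference index (NIR-red)/(NIR+red).

    Healthy and symptomatic leaf tissue has a strong red edge, so the index
    is high over tissue and near zero over the dark background and the flat
    white plate.  Pixels with index > ``threshold`` are kept, connected
    components smaller than ``min_object_px`` removed, holes filled.  The
    index is a ratio, hence invariant to any global illumination scale;
    pixels with NIR + red == 0 get index 0 by convention.
    """
    if not cube.calibrated:
        raise ValueError("segment_by_index requires a calibrated cube")
    red = cube.band(nearest_band(cube.spec, red_nm)).astype(np.float64)
    nir = cube.band(nearest_band(cube.spec, nir_nm)).astype(np.float64)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        index = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0),
                         0.0)
    mask = index > threshold
    if min_object_px > 1 and mask.any():
        labels, n = ndimage.label(mask)
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_object_px)
        mask &= ~np.isin(labels, small[small > 0])
    mask = ndimage.binary_fill_holes(mask)
    return LeafMask(values=mask, source="index")


def mask_iou(a: LeafMask, b: LeafMask) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a.values, b.values).sum()
    if union == 0:
        return 1.0
    inter = np.logical_and(a.values, b.values).sum()
    return float(inter / union)


def _box_downsample(values: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Area-weighted mean over the (possibly fractional) source box that each
    target pixel covers, computed with an integral image."""
    src = values.astype(np.float64)
    H, W = src.shape
    h, w = target
    integral = np.zeros((H + 1, W + 1))
    integral[1:, 1:] = src.cumsum(0).cumsum(1)

    # Fractional prefix sums via linear interpolation of the integral image.
    def interp_rows(I, pos):  # I: (H+1, W+1) -> (len(pos), W+1)
        i0 = np.clip(np.floor(pos).astype(int), 0, I.shape[0] - 1)
        i1 = np.clip(i0 + 1, 0, I.shape[0] - 1)
        t = (pos - i0)[:, None]
        return I[i0] * (1 - t) + I[i1] * t

    ys = np.linspace(0, H, h + 1)
    xs = np.linspace(0, W, w + 1)
    rows = interp_rows(integral, ys)            # (h+1, W+1)
    cols0 = np.clip(np.floor(xs).astype(int), 0, W)
    cols1 = np.clip(cols0 + 1, 0, W)
    t = xs - cols0
    grid = rows[:, cols0] * (1 - t) + rows[:, cols1] * t   # (h+1, w+1)
    sums = grid[1:, 1:] - grid[:-1, 1:] - grid[1:, :-1] + grid[:-1, :-1]
    area = (H / h) * (W / w)
    return sums / area


def downscale_mask(mask: LeafMask, target: tuple[int, int]) -> LeafMask:
    """Downscale a mask by block averaging; ties at 0.5 resolve to leaf."""
    H, W = mask.shape
    h, w = target
    if h > H or w > W:
        raise ValueError("target dims must not exceed source dims")
    frac = _box_downsample(mask.values, (h, w))
    return LeafMask(values=frac >= 0.5, source=mask.source)


def write_mask(mask: LeafMask, path: str | Path) -> Path:
    """Write as 8-bit grayscale (0 background, 255 leaf)."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, mask.values.astype(np.uint8) * np.uint8(255))
    return path


def read_mask(path: str | Path) -> LeafMask:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return LeafMask(values=img >= 128, source="external")
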