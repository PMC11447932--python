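"""Tile grids, per-tile band-mean features and VNIR-SWIR tile pairing.

Each image is divided into fixed-size square tiles (111 x 111 px VNIR,
25 x 25 px SWIR — the same size ratio as the two cameras' images, so the
grids align tile-for-tile).  The feature vector of a tile is the mean
reflectance of its leaf pixels in every band; tiles whose leaf occupancy is
below a minimum fraction are dropped.  A paired feature row concatenates the
VNIR block (184 bands) then the SWIR block (288 bands) in ascending band
order, 472 columns total; the column -> (camera, band, wavelength) map is
fixed and exposed for wavelength ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hsi_io import SWIR, VNIR, CameraSpec, SpectralCube, band_wavelength
from .segmentation import LeafMask

__all__ = [
    "TileGrid",
    "TILE_SIZE",
    "make_tile_grid",
    "extract_tile_features",
    "pair_tiles",
    "feature_columns",
    "feature_column_map",
    "META_COLUMNS",
    "EmptyGridError",
    "PairingError",
]

#: Tile edge length in pixels per camera.
TILE_SIZE = {VNIR.name: 111, SWIR.name: 25}

#: Non-feature columns of a tile feature table.
META_COLUMNS = ["scene_id", "class", "tile_row", "tile_col", "leaf_fraction"]


class EmptyGridError(ValueError):
    """Raised when an image is too small for a single complete tile."""


class PairingError(ValueError):
    """Raised when two tables' tile grids cannot be paired."""


@dataclass(frozen=True)
class TileGrid:
    """Complete-tile grid over an image; partial edge tiles are dropped."""

    tile_size: int
    n_rows: int
    n_cols: int
    origin: tuple[int, int] = (0, 0)

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) half-open pixel bounds of tile (row, col)."""
        r0 = self.origin[0] + row * self.tile_size
        c0 = self.origin[1] + col * self.tile_size
        return r0, r0 + self.tile_size, c0, c0 + self.tile_size


def make_tile_grid(dims: tuple[int, int], tile_size: int) -> TileGrid:
    """Grid of complete tiles by floor division of the image dims."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    h, w = dims
    n_rows, n_cols = h // tile_size, w // tile_size
    if n_rows == 0 or n_cols == 0:
        raise EmptyGridError(
            f"image {h}x{w} holds no complete {tile_size}px tile")
    return TileGrid(tile_size=tile_size, n_rows=n_rows, n_cols=n_cols)


def feature_columns(spec: CameraSpec, prefix_offset: int = 0) -> list[str]:
    return [f"f_{prefix_offset + b + 1:04d}" for b in range(spec.n_bands)]


def feature_column_map(cameras: tuple[CameraSpec, ...] = (VNIR, SWIR)
                       ) -> pd.DataFrame:
    """Deterministic map: feature column -> (camera, 1-based band, nm)."""
    rows = []
    offset = 0
    for spec in cameras:
        for b in range(1, spec.n_bands + 1):
            rows.append({
                "column": f"f_{offset + b:04d}",
                "camera": spec.name,
                "band": b,
                "wavelength_nm": band_wavelength(spec, b),
            })
        offset += spec.n_bands
    return pd.DataFrame(rows)


def extract_tile_features(cube: SpectralCube, mask: LeafMask, grid: TileGrid,
                          min_leaf_fraction: float = 0.5,
                          include_std: bool = False,
                          prefix_offset: int = 0) -> pd.DataFrame:
    """Per-tile mean reflectance over leaf pixels, one row per retained tile.

    Feature b of a tile is the mean of band b over the tile's *leaf* pixels
    only — background never dilutes the spectrum.  Tiles whose leaf fraction
    is below ``min_leaf_fraction`` are dropped.  Per-tile standard deviations
    can be appended behind ``include_std`` but are off by default: they did
    not help classification in the source study's regime.
    """
    if not cube.calibrated:
        raise ValueError("extract_tile_features requires a calibrated cube")
    if mask.shape != cube.shape[:2]:
        raise ValueError(
            f"mask dims {mask.shape} do not match cube {cube.shape[:2]}")
    size = grid.tile_size
    n_bands = cube.spec.n_bands
    cols = feature_columns(cube.spec, prefix_offset)
    rows = []
    feats = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            r0, r1, c0, c1 = grid.bounds(r, c)
            m = mask.values[r0:r1, c0:c1]
            leaf_fraction = m.sum() / (size * size)
            if leaf_fraction < min_leaf_fraction or not m.any():
                continue
            px = cube.values[r0:r1, c0:c1, :][m].astype(np.float64)
            vec = px.mean(axis=0)
            if include_std:
                vec = np.concatenate([vec, px.std(axis=0)])
            rows.append({"scene_id": cube.scene_id,
                         "class": cube.class_label,
                         "tile_row": r, "tile_col": c,
                         "leaf_fraction": float(leaf_fraction)})
            feats.append(vec)
    all_cols = cols + ([f"{c}_sd" for c in cols] if include_std else [])
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    feat = pd.DataFrame(np.array(feats, dtype=np.float64).reshape(
        len(feats), len(all_cols)), columns=all_cols)
    out = pd.concat([meta.reset_index(drop=True), feat], axis=1)
    out.attrs["grid_shape"] = (grid.n_rows, grid.n_cols)
    return out


def pair_tiles(vnir_table: pd.DataFrame, swir_table: pd.DataFrame
               ) -> pd.DataFrame:
    """Concatenate aligned VNIR and SWIR tile rows into combined rows.

    Tables must come from the same scene(s) with equal grid shapes; a pair
    is retained only when both sides passed the leaf-fraction filter.  The
    combined leaf fraction is the VNIR one (higher resolution).
    """
    key = ["scene_id", "tile_row", "tile_col"]
    v_feat = [c for c in vnir_table.columns if c.startswith("f_")]
    s_feat = [c for c in swir_table.columns if c.startswith("f_")]
    if set(v_feat) & set(s_feat):
        raise PairingError(
            "overlapping feature column names; generate the SWIR table with "
            "prefix_offset = VNIR band count")
    shape_v = vnir_table.attrs.get("grid_shape")
    shape_s = swir_table.attrs.get("grid_shape")
    if shape_v is not None and shape_s is not None and shape_v != shape_s:
        scenes = sorted(set(vnir_table.get("scene_id", pd.Series(dtype=str)))
                        | set(swir_table.get("scene_id", pd.Series(dtype=str))))
        raise PairingError(
            f"tile grids differ between cameras ({shape_v} vs {shape_s}) "
            f"for scenes: {', '.join(map(str, scenes))}")
    merged = vnir_table.merge(
        swir_table[key + s_feat + ["leaf_fraction"]],
        on=key, how="inner", suffixes=("", "_swir"))
    merged = merged.drop(columns=["leaf_fraction_swir"])
    return merged[META_COLUMNS + v_feat + s_feat]
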