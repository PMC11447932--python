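"""Greenhouse-mode outputs: tile probability heatmaps, per-plant infestation
scores, visual count categories and their comparison.

A row image covers several plants; the horizontal pixel span of each plant
is known (labelled manually in the field, generated in simulation).  For
every plant and each pest class the score is the percentage of the plant's
tiles for which the three-class model assigns that class a probability
strictly greater than 0.80.  Visual monitoring records insect counts per
plant as ten ordinal categories (0 = none ... 9 = more than 100); the two
assessments are compared by Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classification import GradientBoostedTileClassifier

__all__ = [
    "ProbabilityHeatmap",
    "PlantRegion",
    "PlantScore",
    "heatmap_from_tiles",
    "score_plants",
    "count_to_category",
    "compare_scores",
    "COUNT_CATEGORY_BOUNDS",
]

#: Upper bound (inclusive) of insect-count categories 0..8; category 9 is
#: everything above.
COUNT_CATEGORY_BOUNDS = (0, 5, 10, 15, 20, 30, 50, 70, 100)


@dataclass
class ProbabilityHeatmap:
    """Class-probability vector per tile of one scene.

    ``tiles`` columns: tile_row, tile_col, plus one p_<class> column per
    class; ``tile_size`` and ``origin`` give the grid geometry at the
    resolution of ``camera``.
    """

    tiles: pd.DataFrame
    tile_size: int
    scene_id: str = ""
    origin: tuple[int, int] = (0, 0)

    @property
    def prob_columns(self) -> list[str]:
        return [c for c in self.tiles.columns if c.startswith("p_")]

    def tile_center_col(self) -> np.ndarray:
        """Center column (pixels) of every tile."""
        return (self.origin[1]
                + self.tiles["tile_col"].to_numpy() * self.tile_size
                + self.tile_size / 2.0)


@dataclass
class PlantRegion:
    """Horizontal pixel span [start, end) of one plant in a row image."""

    plant_id: str
    span: tuple[int, int]
    treatment: str = ""


@dataclass
class PlantScore:
    """Per-plant percentage of tiles above the probability threshold."""

    plant_id: str
    scores: dict[str, float] = field(default_factory=dict)  # class -> %
    n_tiles: int = 0
    flagged: bool = False  # True when the span contained no tiles


def heatmap_from_tiles(model: GradientBoostedTileClassifier,
                       table: pd.DataFrame, tile_size: int,
                       scene_id: str = "") -> ProbabilityHeatmap:
    """Predict tile probabilities for one scene's feature table."""
    feat = [c for c in table.columns if c.startswith("f_")]
    proba = model.predict_proba(table[feat].to_numpy(dtype=np.float64))
    tiles = table[["tile_row", "tile_col"]].reset_index(drop=True).copy()
    for i, c in enumerate(model.classes_):
        tiles[f"p_{c}"] = proba[:, i]
    return ProbabilityHeatmap(tiles=tiles, tile_size=tile_size,
                              scene_id=scene_id or str(table["scene_id"].iloc[0]))


def score_plants(heatmap: ProbabilityHeatmap, regions: list[PlantRegion],
                 threshold: float = 0.80,
                 pest_classes: tuple[str, ...] = ("MP", "FO")
                 ) -> list[PlantScore]:
    """Fraction (as %) of each plant's tiles with p_class > threshold.

    A tile belongs to the plant whose span contains the tile's center
    column; the inequality is strict, so a probability exactly at the
    threshold does not count.  Plants whose span holds no tile get a
    flagged, empty score.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    centers = heatmap.tile_center_col()
    out = []
    for region in regions:
        start, end = region.span
        in_span = (centers >= start) & (centers < end)
        n = int(in_span.sum())
        if n == 0:
            warnings.warn(f"plant {region.plant_id}: span contains no tiles")
            out.append(PlantScore(plant_id=region.plant_id, flagged=True))
            continue
        scores = {}
        for cls in pest_classes:
            col = f"p_{cls}"
            if col not in heatmap.tiles.columns:
                continue
            p = heatmap.tiles.loc[in_span, col].to_numpy()
            scores[cls] = 100.0 * float((p > threshold).sum()) / n
        out.append(PlantScore(plant_id=region.plant_id, scores=scores,
                              n_tiles=n))
    return out


def count_to_category(n: int) -> int:
    """Ordinal insect-count category 0-9.

    0 = no insects, 1 = 1-5, 2 = 6-10, 3 = 11-15, 4 = 16-20, 5 = 21-30,
    6 = 31-50, 7 = 51-70, 8 = 71-100, 9 = more than 100.
    """
    if n < 0 or int(n) != n:
        raise ValueError("count must be a nonnegative integer")
    for cat, upper in enumerate(COUNT_CATEGORY_BOUNDS):
        if n <= upper:
            return cat
    return 9


def compare_scores(scores: list[PlantScore], visual: dict[str, int],
                   pest_class: str = "MP") -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between algorithm scores and visual
    count categories for one pest class, plus the paired per-plant table.

    A constant vector on either side yields correlation 0.0 with a
    ``constant`` flag column set in the table.
    """
    rows = []
    for s in scores:
        if s.flagged or pest_class not in s.scores:
            continue
        if s.plant_id in visual:
            rows.append({"plant_id": s.plant_id,
                         "score_pct": s.scores[pest_class],
                         "visual_category": visual[s.plant_id]})
    if not rows:
        raise ValueError("no common plants between scores and visual data")
    table = pd.DataFrame(rows)
    a = table["score_pct"].to_numpy()
    b = table["visual_category"].to_numpy(dtype=float)
    constant = (np.ptp(a) == 0) or (np.ptp(b) == 0) or len(table) < 2
    table["constant_input"] = constant
    if constant:
        return 0.0, table
    rho = stats.spearmanr(a, b).statistic
    return float(rho), table
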