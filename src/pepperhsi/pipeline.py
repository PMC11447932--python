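"""End-to-end orchestration: simulate -> calibrate -> segment -> featurize
-> split -> train -> evaluate -> rank wavelengths -> (greenhouse) score.

Scenes are processed one at a time so the memory footprint stays at a single
cube pair regardless of dataset size.  One global seed deterministically
derives every stage seed (scene seeds, split seed, model seed), so any stage
can be replayed in isolation and a rerun with the same configuration is
identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import synthetic_scenes as syn
from .classification import (ModelConfig, SplitSpec, evaluate, grid_search,
                             split_scenes, train_classifier)
from .hsi_io import SWIR, VNIR, WhiteReference, calibrate_reflectance
from .plant_scoring import (PlantRegion, compare_scores, count_to_category,
                            heatmap_from_tiles, score_plants)
from .segmentation import LeafMask, downscale_mask, segment_by_index
from .tiling_features import (TILE_SIZE, extract_tile_features,
                              make_tile_grid, pair_tiles)
from .wavelength_selection import accuracy_vs_k, rank_wavelengths

__all__ = ["RunConfig", "featurize_scene", "build_feature_table",
           "run_end_to_end", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage seed < 2^31 from the global seed and a stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


class RunConfig(BaseModel):
    """Validated configuration of one end-to-end run."""

    tier: str = "leaf"
    n_per_class: int = Field(30, ge=2)
    swir_dims: tuple[int, int] = (75, 75)
    n_leaves: int = 7
    n_plants: int = 4
    noise_sd: float = Field(0.008, ge=0.0)
    illumination_amplitude: float = Field(0.05, ge=0.0)
    axial_compression: float = Field(0.9, gt=0.0, le=1.0)
    ambient_amplitude: float = Field(0.0, ge=0.0)
    secondary_infestation_fraction: float = Field(0.0, ge=0.0, le=1.0)
    mask_source: str = "index"           # index | truth
    min_leaf_fraction: float = Field(0.5, ge=0.0, le=1.0)
    vnir_tile: int = TILE_SIZE[VNIR.name]
    swir_tile: int = TILE_SIZE[SWIR.name]
    learning_rate: float = Field(0.05, gt=0.0, le=1.0)
    max_depth: int = Field(10, ge=1)
    n_trees: int = Field(100, ge=1)
    do_grid_search: bool = False
    grid_learning_rates: list[float] = [0.01, 0.05, 0.1]
    grid_depths: list[int] = [4, 6, 10, 12]
    grid_trees: list[int] = [50, 100, 200]
    train_fraction: float = Field(0.70, gt=0.0, lt=1.0)
    ks: list[int] = [15]
    score_threshold: float = Field(0.80, gt=0.0, lt=1.0)
    seed: int = 0

    @field_validator("tier")
    @classmethod
    def _tier(cls, v):
        if v not in ("leaf", "plant", "greenhouse"):
            raise ValueError(f"unknown tier {v!r}")
        return v

    @field_validator("mask_source")
    @classmethod
    def _mask(cls, v):
        if v not in ("index", "truth"):
            raise ValueError("mask_source must be 'index' or 'truth'")
        return v

    def scene_base(self) -> syn.SceneConfig:
        return syn.SceneConfig(
            tier=self.tier, swir_dims=tuple(self.swir_dims),
            n_leaves=self.n_leaves, n_plants=self.n_plants,
            noise_sd=self.noise_sd,
            illumination_amplitude=self.illumination_amplitude,
            axial_compression=self.axial_compression,
            ambient_amplitude=self.ambient_amplitude,
            secondary_infestation_fraction=self.secondary_infestation_fraction)

    def model_config_(self) -> ModelConfig:
        return ModelConfig(learning_rate=self.learning_rate,
                           max_depth=self.max_depth, n_trees=self.n_trees,
                           seed=stage_seed(self.seed, "model"))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def featurize_scene(scene: syn.Scene, mask_source: str = "index",
                    min_leaf_fraction: float = 0.5,
                    include_std: bool = False) -> pd.DataFrame:
    """Calibrate both cubes of a scene, build the leaf mask at VNIR
    resolution, downscale it for SWIR, extract per-tile band means and pair
    the two cameras' tiles into 472-column feature rows."""
    vnir = calibrate_reflectance(
        scene.vnir, WhiteReference.from_cube(scene.vnir,
                                             scene.white_region_vnir))
    swir = calibrate_reflectance(
        scene.swir, WhiteReference.from_cube(scene.swir,
                                             scene.white_region_swir))
    if mask_source == "truth":
        mask_v = LeafMask(scene.truth_mask_vnir, source="truth")
    elif mask_source == "index":
        mask_v = segment_by_index(vnir)
    else:
        raise ValueError(f"unknown mask source {mask_source!r}")
    mask_s = downscale_mask(mask_v, swir.shape[:2])
    grid_v = make_tile_grid(vnir.shape[:2], TILE_SIZE[VNIR.name])
    grid_s = make_tile_grid(swir.shape[:2], TILE_SIZE[SWIR.name])
    tv = extract_tile_features(vnir, mask_v, grid_v, min_leaf_fraction,
                               include_std=include_std)
    ts = extract_tile_features(swir, mask_s, grid_s, min_leaf_fraction,
                               include_std=include_std,
                               prefix_offset=VNIR.n_bands)
    return pair_tiles(tv, ts)


def build_feature_table(n_per_class: int, tier: str, seed: int,
                        base: syn.SceneConfig | None = None,
                        mask_source: str = "index",
                        min_leaf_fraction: float = 0.5,
                        keep_scenes: bool = False
                        ) -> tuple[pd.DataFrame, pd.DataFrame,
                                   list[syn.Scene] | None]:
    """Generate a balanced dataset in memory and featurize it scene by
    scene.  Returns (feature table, manifest, scenes or None)."""
    tables = []
    manifest_rows = []
    scenes = [] if keep_scenes else None
    for scene_id, cfg in syn.dataset_configs(n_per_class, tier, seed, base):
        scene = syn.generate_scene(cfg, scene_id)
        tables.append(featurize_scene(scene, mask_source, min_leaf_fraction))
        manifest_rows.append({
            "scene_id": scene_id, "tier": tier, "class": cfg.class_label,
            "symptom_fraction": scene.symptom_fraction,
            "insect_count": scene.insect_count, "seed": cfg.seed})
        if keep_scenes:
            scenes.append(scene)
    nonempty = [t for t in tables if len(t)]
    table = pd.concat(nonempty or tables[:1], ignore_index=True)
    return table, pd.DataFrame(manifest_rows), scenes


def run_end_to_end(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write artifacts; returns the summary dict.

    Artifacts: features.csv, report.json / report.txt, ranking.csv,
    accuracy_vs_k.csv, plant_scores.csv (greenhouse tier) and summary.json,
    all stamped with the configuration hash and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.model_dump(),
                     "config_hash": config.config_hash(),
                     "seed": config.seed}

    keep = config.tier == "greenhouse"
    table, manifest, scenes = build_feature_table(
        config.n_per_class, config.tier, stage_seed(config.seed, "scenes"),
        base=config.scene_base(), mask_source=config.mask_source,
        min_leaf_fraction=config.min_leaf_fraction, keep_scenes=keep)
    table.to_csv(out_dir / "features.csv", index=False)
    summary["n_scenes"] = len(manifest)
    summary["n_tiles"] = len(table)

    split = SplitSpec(train_fraction=config.train_fraction,
                      seed=stage_seed(config.seed, "split"))
    train_ids, test_ids = split_scenes(manifest, split)
    train = table[table["scene_id"].isin(train_ids)]
    test = table[table["scene_id"].isin(test_ids)]

    model_cfg = config.model_config_()
    if config.do_grid_search:
        grid = [ModelConfig(lr, d, t, model_cfg.seed)
                for lr in config.grid_learning_rates
                for d in config.grid_depths
                for t in config.grid_trees]
        model_cfg = grid_search(train, grid,
                                seed=stage_seed(config.seed, "folds"))
        summary["grid_search_selected"] = dataclasses.asdict(model_cfg)
    model = train_classifier(train, model_cfg)

    report = evaluate(model, test, level="image")
    summary["image_accuracy"] = report.accuracy
    (out_dir / "report.json").write_text(json.dumps(report.rounded(), indent=2))
    (out_dir / "report.txt").write_text(report.to_text() + "\n")

    ranking = rank_wavelengths(model)
    ranking.table.to_csv(out_dir / "ranking.csv", index=False)
    ks = [k for k in config.ks if k <= sum(
        1 for c in table.columns if c.startswith("f_"))]
    if ks:
        curve = accuracy_vs_k(table, sorted(ks), model_cfg, split)
        curve.to_csv(out_dir / "accuracy_vs_k.csv", index=False)
        summary["accuracy_vs_k"] = curve.to_dict("records")

    if config.tier == "greenhouse":
        score_rows = []
        plant_scores: dict[str, list] = {"MP": [], "FO": []}
        plant_visual: dict[str, dict[str, int]] = {"MP": {}, "FO": {}}
        for scene in scenes:
            scene_tiles = table[table["scene_id"] == scene.scene_id]
            if scene_tiles.empty:
                continue
            hm = heatmap_from_tiles(model, scene_tiles,
                                    TILE_SIZE[VNIR.name], scene.scene_id)
            regions = [PlantRegion(f"{scene.scene_id}_p{i}", span,
                                   treatment=scene.plant_labels[i])
                       for i, span in enumerate(scene.plant_spans)]
            for i, ps in enumerate(score_plants(hm, regions,
                                                config.score_threshold)):
                treatment = scene.plant_labels[i]
                for cls, pct in ps.scores.items():
                    score_rows.append({"scene_id": scene.scene_id,
                                       "plant_id": ps.plant_id,
                                       "treatment": treatment,
                                       "pest_class": cls, "score_pct": pct,
                                       "n_tiles": ps.n_tiles})
                # Compare each pest's score against visual counts on the
                # plants actually carrying that pest.
                if not ps.flagged and treatment in plant_scores:
                    plant_scores[treatment].append(ps)
                    plant_visual[treatment][ps.plant_id] = count_to_category(
                        scene.plant_counts[i])
        pd.DataFrame(score_rows).to_csv(out_dir / "plant_scores.csv",
                                        index=False)
        correlations = {}
        for cls in ("MP", "FO"):
            if len(plant_scores[cls]) >= 2:
                rho, _ = compare_scores(plant_scores[cls],
                                        plant_visual[cls], cls)
                correlations[cls] = rho
        summary["score_visual_spearman"] = correlations

    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary
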