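import hashlib

import numpy as np
import pytest

from pepperhsi.hsi_io import SWIR, VNIR
from pepperhsi.synthetic_scenes import (COVERAGE, ConfigError, ParameterError,
                                        SceneConfig, SignatureParams,
                                        generate_dataset,
                                        generate_greenhouse_scene,
                                        generate_leaf_scene,
                                        generate_plant_scene,
                                        healthy_spectrum)

SMALL = {"swir_dims": (75, 75)}


class TestSignature:
    def test_red_edge_on_vnir_grid(self):
        p = SignatureParams()
        r = healthy_spectrum(p, VNIR.wavelengths)
        at = lambda nm: r[np.argmin(np.abs(VNIR.wavelengths - nm))]
        assert at(760) > at(680)

    def test_water_absorption_on_swir_grid(self):
        p = SignatureParams()
        r = healthy_spectrum(p, SWIR.wavelengths)
        at = lambda nm: r[np.argmin(np.abs(SWIR.wavelengths - nm))]
        assert at(1650) > at(1930)

    def test_all_spectra_in_unit_interval(self):
        p = SignatureParams()
        wl = np.concatenate([VNIR.wavelengths, SWIR.wavelengths])
        for f in (p.healthy, p.honeydew, p.spot, p.speck, p.stem):
            r = f(wl)
            assert r.min() >= 0.0 and r.max() <= 1.0

    def test_zero_amplitude_collapses_symptoms_to_healthy(self):
        p = SignatureParams(symptom_amplitude=0.0)
        wl = VNIR.wavelengths
        np.testing.assert_allclose(p.honeydew(wl), p.healthy(wl))
        np.testing.assert_allclose(p.spot(wl), p.healthy(wl))
        np.testing.assert_allclose(p.speck(wl), p.healthy(wl))

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            healthy_spectrum(SignatureParams(nir_plateau=2.0),
                             VNIR.wavelengths)

    def test_wavelengths_outside_model_range(self):
        with pytest.raises(ValueError):
            healthy_spectrum(SignatureParams(), np.array([300.0]))


class TestLeafScene:
    def test_uc_has_no_symptoms(self, leaf_scene_uc):
        assert leaf_scene_uc.symptom_fraction == 0.0
        assert leaf_scene_uc.truth_mask_vnir.any()

    @pytest.mark.parametrize("label", ["MP", "FO"])
    def test_coverage_matches_study_mean_at_zero_sd(self, label):
        """At sd=0 the realized symptomatic fraction hits the study's
        printed mean coverage within one percentage point."""
        cfg = SceneConfig(class_label=label, tier="leaf", coverage_sd=0.0,
                          seed=9, **SMALL)
        scene = generate_leaf_scene(cfg)
        assert scene.symptom_fraction == pytest.approx(
            COVERAGE[label][0], abs=0.01)

    def test_determinism_byte_identical(self):
        cfg = SceneConfig(class_label="FO", tier="leaf", seed=33, **SMALL)
        a, b = generate_leaf_scene(cfg), generate_leaf_scene(cfg)
        np.testing.assert_array_equal(a.vnir.values, b.vnir.values)
        np.testing.assert_array_equal(a.swir.values, b.swir.values)
        np.testing.assert_array_equal(a.symptom_map_vnir, b.symptom_map_vnir)
        assert a.symptom_fraction == b.symptom_fraction
        assert a.insect_count == b.insect_count

    def test_cameras_are_coregistered(self, leaf_scene_mp):
        """The same geometry rasterized at both resolutions: the SWIR truth
        mask matches the block-downscaled VNIR truth mask closely."""
        from pepperhsi.segmentation import LeafMask, downscale_mask, mask_iou

        down = downscale_mask(LeafMask(leaf_scene_mp.truth_mask_vnir,
                                       source="truth"),
                              leaf_scene_mp.truth_mask_swir.shape)
        iou = mask_iou(down, LeafMask(leaf_scene_mp.truth_mask_swir,
                                      source="truth"))
        assert iou > 0.9

    def test_white_patch_embedded(self, leaf_scene_uc):
        r0, r1, c0, c1 = leaf_scene_uc.white_region_vnir
        assert r1 > r0 and c1 > c0
        # raw white pixels are bright relative to background
        white = leaf_scene_uc.vnir.values[r0:r1, c0:c1].mean()
        bg = leaf_scene_uc.vnir.values[-5:, -5:].mean()
        assert white > 5 * bg

    def test_scene_too_small_rejected(self):
        with pytest.raises(ConfigError):
            SceneConfig(tier="leaf", swir_dims=(25, 25))

    def test_dims_must_respect_camera_ratio(self):
        with pytest.raises(ConfigError):
            SceneConfig(tier="leaf", swir_dims=(52, 52))


class TestPlantScene:
    def test_contains_stem_and_leaves(self, plant_scene_mp):
        from pepperhsi.synthetic_scenes import T_LEAF, T_STEM
        assert (plant_scene_mp.symptom_map_vnir == T_STEM).any()
        assert (plant_scene_mp.symptom_map_vnir == T_LEAF).any()

    def test_determinism(self):
        cfg = SceneConfig(class_label="MP", tier="plant", seed=77, **SMALL)
        a, b = generate_plant_scene(cfg), generate_plant_scene(cfg)
        np.testing.assert_array_equal(a.vnir.values, b.vnir.values)

    def test_occlusion_lowers_visible_symptom_fraction(self):
        """Mean visible symptomatic fraction over plant scenes falls below
        the dissected-leaf coverage mean (canopy occlusion + gradient)."""
        fracs = []
        for seed in range(20):
            cfg = SceneConfig(class_label="MP", tier="plant", seed=1000 + seed,
                              **SMALL)
            fracs.append(generate_plant_scene(cfg).symptom_fraction)
        assert np.mean(fracs) < COVERAGE["MP"][0]


class TestGreenhouseScene:
    def test_degenerate_degradation_is_concatenation(self):
        """Compression 1, no jitter/ambient: the row is the plants side by
        side; spans partition the occupied width without overlap."""
        cfg = SceneConfig(class_label="UC", tier="greenhouse", n_plants=3,
                          axial_compression=1.0, scale_jitter=0.0,
                          ambient_amplitude=0.0, seed=5, **SMALL)
        scene = generate_greenhouse_scene(cfg)
        h_v, w_v = scene.symptom_map_vnir.shape
        pw_v = cfg.vnir_dims[1]
        assert w_v == 111 + 3 * pw_v  # white strip + 3 plants
        spans = scene.plant_spans
        assert spans[0][0] == 111
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 == b0  # contiguous, non-overlapping
        assert spans[-1][1] == w_v

    def test_compression_shrinks_scan_axis(self):
        cfg = SceneConfig(class_label="UC", tier="greenhouse", n_plants=2,
                          axial_compression=0.8, seed=5, **SMALL)
        scene = generate_greenhouse_scene(cfg)
        full = 111 + 2 * cfg.vnir_dims[1]
        assert scene.symptom_map_vnir.shape[1] == round(full * 0.8)

    def test_secondary_infestation_adds_honeydew_to_fo(self):
        from pepperhsi.synthetic_scenes import T_HONEYDEW, T_SPOT
        cfg = SceneConfig(class_label="FO", tier="greenhouse", n_plants=2,
                          secondary_infestation_fraction=1.0, seed=11,
                          **SMALL)
        scene = generate_greenhouse_scene(cfg)
        assert (scene.symptom_map_vnir == T_SPOT).any()
        assert (scene.symptom_map_vnir == T_HONEYDEW).any()


class TestDataset:
    def test_manifest_balanced_and_deterministic(self, tmp_path):
        m1 = generate_dataset(1, "leaf", seed=3, out_dir=tmp_path / "a",
                              base=SceneConfig(tier="leaf", **SMALL))
        m2 = generate_dataset(1, "leaf", seed=3, out_dir=tmp_path / "b",
                              base=SceneConfig(tier="leaf", **SMALL))
        assert len(m1) == 3
        assert m1["class"].value_counts().nunique() == 1
        # identical manifests (modulo paths) and identical cube bytes
        drop = ["vnir_path", "swir_path", "mask_path"]
        assert m1.drop(columns=drop).equals(m2.drop(columns=drop))
        for p1, p2 in zip(m1["vnir_path"], m2["vnir_path"]):
            h1 = hashlib.md5(open(p1.replace(".hdr", ".raw"), "rb").read())
            h2 = hashlib.md5(open(p2.replace(".hdr", ".raw"), "rb").read())
            assert h1.hexdigest() == h2.hexdigest()

    def test_roundtrip_through_disk(self, tmp_path):
        from pepperhsi.hsi_io import read_cube
        m = generate_dataset(1, "leaf", seed=4, out_dir=tmp_path,
                             base=SceneConfig(tier="leaf", **SMALL))
        cube = read_cube(m["vnir_path"].iloc[0])
        assert cube.spec.n_bands == 184
        assert not cube.calibrated


def test_separability_dial():
    """With default symptom amplitudes and no noise, between-class spectral
    distance exceeds 10x the within-class distance."""
    means = {}
    for label in ("UC", "MP", "FO"):
        vecs = []
        for i in range(3):
            cfg = SceneConfig(class_label=label, tier="leaf", noise_sd=0.0,
                              illumination_amplitude=0.0, seed=500 + i,
                              **SMALL)
            s = generate_leaf_scene(cfg)
            from pepperhsi.pipeline import featurize_scene
            t = featurize_scene(s, mask_source="truth")
            vecs.append(t[[c for c in t.columns
                           if c.startswith("f_")]].mean().to_numpy())
        means[label] = vecs
    def dist(a, b):
        return np.linalg.norm(np.asarray(a) - np.asarray(b))
    within = []
    for label, vecs in means.items():
        within += [dist(vecs[i], vecs[j])
                   for i in range(3) for j in range(i + 1, 3)]
    between = []
    labels = list(means)
    for i in range(3):
        for j in range(i + 1, 3):
            between += [dist(a, b) for a in means[labels[i]]
                        for b in means[labels[j]]]
    assert np.mean(between) > 10 * np.mean(within)
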