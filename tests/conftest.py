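import numpy as np
import pytest

from pepperhsi.hsi_io import SpectralCube
from pepperhsi.synthetic_scenes import (SceneConfig, generate_leaf_scene,
                                        generate_plant_scene)

#: Compact scene geometry used by most tests: SWIR 75x75 -> VNIR 333x333,
#: i.e. a 3x3 grid of tiles per camera.
SMALL = {"swir_dims": (75, 75)}


@pytest.fixture(scope="session")
def leaf_scene_uc():
    return generate_leaf_scene(SceneConfig(class_label="UC", tier="leaf",
                                           seed=101, **SMALL), "uc0")


@pytest.fixture(scope="session")
def leaf_scene_mp():
    return generate_leaf_scene(SceneConfig(class_label="MP", tier="leaf",
                                           seed=102, **SMALL), "mp0")


@pytest.fixture(scope="session")
def leaf_scene_fo():
    return generate_leaf_scene(SceneConfig(class_label="FO", tier="leaf",
                                           seed=103, **SMALL), "fo0")


@pytest.fixture(scope="session")
def plant_scene_mp():
    return generate_plant_scene(SceneConfig(class_label="MP", tier="plant",
                                            seed=104, **SMALL), "mpp0")


@pytest.fixture
def tiny_cube():
    """4x4x5 cube with deterministic values, for I/O and calibration tests."""
    rng = np.random.default_rng(7)
    from pepperhsi.hsi_io import CameraSpec
    spec = CameraSpec("tiny", n_bands=5, wl_min=500.0, wl_max=900.0,
                      spectral_resolution=100.0, spatial_width=4)
    values = rng.uniform(0.1, 1.0, size=(4, 4, 5)).astype(np.float32)
    return SpectralCube(values=values, spec=spec, scene_id="tiny")


@pytest.fixture(scope="session")
def small_feature_table():
    """Paired tile features for a small balanced leaf dataset (4/class)."""
    from pepperhsi.pipeline import build_feature_table

    table, manifest, _ = build_feature_table(
        4, "leaf", seed=42, base=SceneConfig(tier="leaf", **SMALL))
    return table, manifest
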