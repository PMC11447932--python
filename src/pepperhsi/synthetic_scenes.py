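"""Synthetic paired VNIR/SWIR scene generator with ground truth.

The study's raw images are not public, so the pipeline is exercised on
simulated scenes that carry the statistical structure the analysis assumes:

* a parametric healthy bell-pepper leaf reflectance spectrum (green peak,
  chlorophyll absorption, red edge, NIR plateau, 1450/1930 nm water
  absorption, SWIR tail decline);
* aphid (MP, *Myzus persicae*) scenes where honeydew covers on average
  90.62 +/- 9.19 % of the leaf area, modelled as a broadband specular gloss
  plus sugar absorption features near 1340/1518/1833 nm;
* thrips (FO, *Frankliniella occidentalis*) scenes where feeding spots and
  feces cover 9.56 +/- 4.15 % of the leaf area, modelled as whitened,
  chlorophyll-flattened spots plus dark broadband specks;
* three scene tiers: a single dissected leaf, a whole plant with
  overlapping leaves and a stem, and a greenhouse row of plants with axial
  compression, scale jitter and ambient light.

Geometry is defined in continuous normalized coordinates and rasterized at
each camera's native resolution, so the two cubes of a scene are co-registered
by construction.  Every scene embeds a white reference patch and is returned
as *raw* (uncalibrated) radiance; downstream stages perform the calibration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hsi_io import (CLASS_LABELS, SWIR, VNIR, CameraSpec, SpectralCube,
                     nearest_band, write_cube)

__all__ = [
    "SignatureParams",
    "SceneConfig",
    "Scene",
    "healthy_spectrum",
    "generate_leaf_scene",
    "generate_plant_scene",
    "generate_greenhouse_scene",
    "generate_scene",
    "generate_dataset",
    "MEAN_INSECTS",
]

# Pixel-type codes shared by both cameras' type maps.
T_BG, T_LEAF, T_HONEYDEW, T_SPOT, T_SPECK, T_STEM, T_WHITE = range(7)

#: Exact integer VNIR:SWIR size ratio implied by the 111:25 tile-size ratio.
VNIR_SWIR_RATIO = (111, 25)

#: Mean +/- SD insects per leaf observed in the controlled experiment,
#: recorded as scene metadata for comparison with visual count categories.
MEAN_INSECTS = {"MP": (46.55, 62.55), "FO": (1.8, 1.25), "UC": (0.0, 0.0)}

#: Controlled-condition symptom coverage of leaf area (fraction): mean, SD.
COVERAGE = {"MP": (0.9062, 0.0919), "FO": (0.0956, 0.0415), "UC": (0.0, 0.0)}

#: Default planted channels for the diagnostic planted-band mode: one VNIR
#: and two SWIR wavelengths in pest-relevant spectral regions.
PLANTED_DEFAULT = (502.0, 1340.0, 1833.0)


class ParameterError(ValueError):
    """Raised when signature parameters produce spectra outside [0, 1]."""


class ConfigError(ValueError):
    """Raised for inconsistent scene configurations."""


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SignatureParams:
    """Degrees of freedom of the spectral signature model.

    Healthy-leaf parameters follow the canonical shape of green vegetation
    reflectance; symptom perturbations are anchored to the wavelength regions
    that discriminate the two pests (sugar/water features in the SWIR for
    honeydew, raised and flattened visible reflectance for thrips feeding,
    broadband darkening for feces).  ``symptom_amplitude`` scales all symptom
    perturbations at once; 0 renders the three classes spectrally identical
    (the negative control).  ``planted_wavelengths`` switches the generator to
    a diagnostic mode in which broadband symptom perturbations are suppressed
    and each symptom type differs from healthy tissue at exactly one spectral
    channel — used to verify importance-based wavelength recovery.
    """

    vis_base: float = 0.04
    green_peak_height: float = 0.08
    green_peak_center: float = 550.0
    green_peak_width: float = 28.0
    red_edge_center: float = 715.0
    red_edge_width: float = 11.0
    nir_plateau: float = 0.46
    water_970_depth: float = 0.06
    water_1200_depth: float = 0.10
    water_1450_depth: float = 0.55
    water_1930_depth: float = 0.75
    swir_decay_center: float = 2050.0
    swir_decay_width: float = 320.0
    # Honeydew (MP): additive gloss + sugar absorption features.
    honeydew_gloss: float = 0.10
    honeydew_feature_depth: float = 0.09
    honeydew_features: tuple[float, ...] = (1340.0, 1518.0, 1833.0, 980.0)
    honeydew_feature_width: float = 22.0
    # Thrips feeding spot (FO): blend toward a flat bright "whitish" level.
    # Whitening is confined to the visible range (emptied cells scatter more
    # light where pigments absorbed; the NIR plateau is scattering-dominated
    # already), so spots stay within the leaf mask of red/NIR index methods.
    spot_mix: float = 0.55
    spot_level: float = 0.38
    spot_rolloff_nm: float = 720.0
    # Feces speck (FO): broadband low reflectance.
    speck_level: float = 0.06
    symptom_amplitude: float = 1.0
    # Diagnostic planted-band mode (see class docstring).
    planted_wavelengths: tuple[float, ...] | None = None
    planted_amplitude: float = 0.15

    def healthy(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        vis = self.vis_base + self.green_peak_height * _gauss(
            wl, self.green_peak_center, self.green_peak_width)
        edge = _logistic((wl - self.red_edge_center) / self.red_edge_width)
        dips = (self.water_970_depth * _gauss(wl, 970.0, 35.0)
                + self.water_1200_depth * _gauss(wl, 1200.0, 45.0)
                + self.water_1450_depth * _gauss(wl, 1450.0, 55.0)
                + self.water_1930_depth * _gauss(wl, 1930.0, 85.0))
        decay = 0.25 + 0.75 * _logistic(
            -(wl - self.swir_decay_center) / self.swir_decay_width)
        r = vis + self.nir_plateau * edge * decay * np.clip(1.0 - dips, 0.0, None)
        self._check_range(r, "healthy")
        return r

    def honeydew(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        base = self.healthy(wl)
        if self.planted_wavelengths is not None:
            return base
        a = self.symptom_amplitude
        delta = self.honeydew_gloss * np.ones_like(wl)
        for center in self.honeydew_features:
            delta -= self.honeydew_feature_depth * _gauss(
                wl, center, self.honeydew_feature_width)
        r = np.clip(base + a * delta, 0.0, 1.0)
        return r

    def spot(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        base = self.healthy(wl)
        if self.planted_wavelengths is not None:
            return base
        mix = (self.symptom_amplitude * self.spot_mix
               * _logistic((self.spot_rolloff_nm - wl) / 15.0))
        return (1.0 - mix) * base + mix * self.spot_level

    def speck(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=np.float64)
        base = self.healthy(wl)
        if self.planted_wavelengths is not None:
            return base
        a = self.symptom_amplitude
        return (1.0 - a) * base + a * self.speck_level

    def stem(self, wavelengths: np.ndarray) -> np.ndarray:
        # Woody tissue: brownish, reflectance rising slowly with wavelength
        # and no red edge, so vegetation-index masks exclude it.
        wl = np.asarray(wavelengths, dtype=np.float64)
        return 0.12 + 0.10 * _logistic((wl - 1000.0) / 400.0)

    @staticmethod
    def background(wavelengths: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(wavelengths, dtype=np.float64), 0.02)

    @staticmethod
    def white(wavelengths: np.ndarray) -> np.ndarray:
        return np.ones_like(np.asarray(wavelengths, dtype=np.float64))

    @staticmethod
    def _check_range(r: np.ndarray, which: str) -> None:
        if np.any(r < 0.0) or np.any(r > 1.0):
            raise ParameterError(f"{which} spectrum leaves [0, 1]")

    def spectra_lut(self, spec: CameraSpec) -> np.ndarray:
        """(7, n_bands) lookup table of reflectance per pixel type."""
        wl = spec.wavelengths
        lut = np.stack([
            self.background(wl), self.healthy(wl), self.honeydew(wl),
            self.spot(wl), self.speck(wl), self.stem(wl), self.white(wl),
        ])
        if self.planted_wavelengths is not None:
            # Channel roles: [0] aphid-specific (honeydew only),
            # [1] thrips-specific (spot + speck), [2] shared symptom channel
            # perturbed by every symptom type.  Each channel is then the
            # single best split for one of the three classes, so importance
            # ranking should recover all of them.
            w = self.planted_wavelengths
            assignment = [(T_HONEYDEW, w[0])]
            if len(w) > 1:
                assignment += [(T_SPOT, w[1]), (T_SPECK, w[1])]
            if len(w) > 2:
                assignment += [(T_HONEYDEW, w[2]), (T_SPOT, w[2]),
                               (T_SPECK, w[2])]
            for t_code, planted in assignment:
                if not spec.wl_min <= planted <= spec.wl_max:
                    continue
                b = nearest_band(spec, planted) - 1
                lut[t_code, b] = np.clip(
                    lut[t_code, b] + self.symptom_amplitude
                    * self.planted_amplitude, 0.0, 1.0)
        return lut


def healthy_spectrum(params: SignatureParams,
                     wavelengths: np.ndarray) -> np.ndarray:
    """Healthy bell-pepper leaf reflectance on an arbitrary wavelength grid."""
    wl = np.asarray(wavelengths, dtype=np.float64)
    if np.any(wl < 400.0) or np.any(wl > 2511.0):
        raise ValueError("wavelengths outside the 400-2511 nm model range")
    return params.healthy(wl)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic scene (or of a dataset's scenes).

    Spatial dimensions are given at SWIR resolution; VNIR dimensions are
    derived by the exact 111:25 size ratio so the two tile grids align.
    ``coverage_mean``/``coverage_sd`` default to the controlled-condition
    symptom statistics of the scene's class.  The seed fixes the scene
    byte-for-byte.
    """

    class_label: str = "UC"
    tier: str = "leaf"  # leaf | plant | greenhouse
    swir_dims: tuple[int, int] = (75, 75)
    n_leaves: int = 7
    n_plants: int = 4
    coverage_mean: float | None = None
    coverage_sd: float | None = None
    noise_sd: float = 0.008
    illumination_amplitude: float = 0.05
    blob_radius: float = 0.018     # symptom disk radius, normalized units
    spot_share: float = 0.8        # FO symptom mix: spots vs feces specks
    axial_compression: float = 0.9
    scale_jitter: float = 0.15
    ambient_amplitude: float = 0.0
    secondary_infestation_fraction: float = 0.0
    params: SignatureParams = field(default_factory=SignatureParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ConfigError(f"unknown class {self.class_label!r}")
        if self.tier not in ("leaf", "plant", "greenhouse"):
            raise ConfigError(f"unknown tier {self.tier!r}")
        if min(self.swir_dims) < 40:
            raise ConfigError("scene too small to hold a leaf and white patch")
        num, den = VNIR_SWIR_RATIO
        for d in self.swir_dims:
            if (d * num) % den:
                raise ConfigError(
                    f"SWIR dim {d} does not map to an integer VNIR dim "
                    f"under the {num}:{den} ratio")

    @property
    def vnir_dims(self) -> tuple[int, int]:
        num, den = VNIR_SWIR_RATIO
        return (self.swir_dims[0] * num // den, self.swir_dims[1] * num // den)

    @property
    def coverage(self) -> tuple[float, float]:
        mean, sd = COVERAGE[self.class_label]
        return (self.coverage_mean if self.coverage_mean is not None else mean,
                self.coverage_sd if self.coverage_sd is not None else sd)


@dataclass
class Scene:
    """One generated scene: raw paired cubes plus full ground truth."""

    scene_id: str
    class_label: str
    tier: str
    vnir: SpectralCube
    swir: SpectralCube
    truth_mask_vnir: np.ndarray          # bool, leaf tissue incl. symptoms
    truth_mask_swir: np.ndarray
    symptom_map_vnir: np.ndarray         # uint8 pixel-type codes
    symptom_map_swir: np.ndarray
    white_region_vnir: tuple[int, int, int, int]
    white_region_swir: tuple[int, int, int, int]
    symptom_fraction: float              # realized, at VNIR resolution
    insect_count: int
    plant_spans: list[tuple[int, int]] | None = None
    plant_labels: list[str] | None = None
    plant_fractions: list[float] | None = None
    plant_counts: list[int] | None = None


# ---------------------------------------------------------------------------
# Geometry rasterization in normalized [0, 1]^2 coordinates.


def _grid(dims: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    h, w = dims
    yy = (np.arange(h, dtype=np.float64)[:, None] + 0.5) / h
    xx = (np.arange(w, dtype=np.float64)[None, :] + 0.5) / w
    return yy, xx


def _ellipse(dims, cy, cx, ry, rx, angle) -> np.ndarray:
    yy, xx = _grid(dims)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0


def _paint_disks(type_map: np.ndarray, disks, code_of) -> None:
    """Rasterize (cy, cx, r, kind) disks into a type map, in order."""
    h, w = type_map.shape
    for cy, cx, r, kind in disks:
        r0 = max(0, int((cy - r) * h) - 1)
        r1 = min(h, int((cy + r) * h) + 2)
        c0 = max(0, int((cx - r) * w) - 1)
        c1 = min(w, int((cx + r) * w) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = (np.arange(r0, r1, dtype=np.float64)[:, None] + 0.5) / h
        xx = (np.arange(c0, c1, dtype=np.float64)[None, :] + 0.5) / w
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        patch = type_map[r0:r1, c0:c1]
        patch[inside & (patch == T_LEAF)] = code_of(kind)


def _carve_gaps(rng, leaf_mask_vnir, type_map_vnir, target_fraction,
                config: SceneConfig, radius_scale: float = 1.0) -> list:
    """Inverse blob growth for heavy honeydew coverage: the leaf is first
    covered entirely, then clustered *healthy gaps* (where the film did not
    reach) are carved out until the symptomatic fraction drops to the
    target.  Clustered gaps give individual tiles a realistic spread of
    coverage around the per-leaf mean.  Returns the gap disk list for
    replay at the other camera's resolution."""
    leaf_px = int(leaf_mask_vnir.sum())
    type_map_vnir[leaf_mask_vnir] = T_HONEYDEW
    gaps: list[tuple[float, float, float]] = []
    if leaf_px == 0 or target_fraction >= 1.0:
        return gaps
    h, w = leaf_mask_vnir.shape
    rows, cols = np.nonzero(leaf_mask_vnir)
    lo_r, hi_r = rows.min(), rows.max()
    lo_c, hi_c = cols.min(), cols.max()
    healthy_target = 1.0 - target_fraction
    healthy = np.zeros_like(leaf_mask_vnir)
    frac = 0.0
    base_r = config.blob_radius * radius_scale
    for _ in range(40000):
        if frac >= healthy_target:
            break
        cy = rng.uniform((lo_r + 0.5) / h, (hi_r + 0.5) / h)
        cx = rng.uniform((lo_c + 0.5) / w, (hi_c + 0.5) / w)
        if not leaf_mask_vnir[min(int(cy * h), h - 1), min(int(cx * w), w - 1)]:
            continue
        r = base_r
        if healthy_target - frac > 0.12 and rng.uniform() < 0.3:
            r = base_r * 3.5
        gaps.append((cy, cx, r))
        r0 = max(0, int((cy - r) * h) - 1)
        r1 = min(h, int((cy + r) * h) + 2)
        c0 = max(0, int((cx - r) * w) - 1)
        c1 = min(w, int((cx + r) * w) + 2)
        yy = (np.arange(r0, r1, dtype=np.float64)[:, None] + 0.5) / h
        xx = (np.arange(c0, c1, dtype=np.float64)[None, :] + 0.5) / w
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        sub = inside & leaf_mask_vnir[r0:r1, c0:c1]
        type_map_vnir[r0:r1, c0:c1][sub] = T_LEAF
        healthy[r0:r1, c0:c1] |= sub
        frac = healthy.sum() / leaf_px
    return gaps


def _replay_gaps(type_map, leaf_mask, gaps) -> None:
    """Apply fill + carved gaps at another resolution."""
    type_map[leaf_mask] = T_HONEYDEW
    h, w = type_map.shape
    for cy, cx, r in gaps:
        r0 = max(0, int((cy - r) * h) - 1)
        r1 = min(h, int((cy + r) * h) + 2)
        c0 = max(0, int((cx - r) * w) - 1)
        c1 = min(w, int((cx + r) * w) + 2)
        if r0 >= r1 or c0 >= c1:
            continue
        yy = (np.arange(r0, r1, dtype=np.float64)[:, None] + 0.5) / h
        xx = (np.arange(c0, c1, dtype=np.float64)[None, :] + 0.5) / w
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        sub = inside & leaf_mask[r0:r1, c0:c1]
        type_map[r0:r1, c0:c1][sub] = T_LEAF


def _grow_symptoms(rng, leaf_mask_vnir, type_map_vnir, target_fraction,
                   config: SceneConfig, symptom_code: str,
                   radius_scale: float = 1.0) -> list:
    """Grow symptom blobs (union of random disks) on one leaf until the
    symptomatic fraction of its visible area is within one percentage point
    of the target.  Returns the disk list for re-rasterization at SWIR
    resolution.  ``symptom_code`` is 'MP' (honeydew) or 'FO' (spot/speck mix).
    """
    leaf_px = int(leaf_mask_vnir.sum())
    disks: list[tuple[float, float, float, str]] = []
    if leaf_px == 0 or target_fraction <= 0.0:
        return disks
    h, w = leaf_mask_vnir.shape
    rows, cols = np.nonzero(leaf_mask_vnir)
    lo_r, hi_r = rows.min(), rows.max()
    lo_c, hi_c = cols.min(), cols.max()
    covered = np.zeros_like(leaf_mask_vnir)
    frac = 0.0
    # Each disk adds < 1 pp of the leaf area, so stopping at the first
    # crossing leaves the realized fraction within 1 pp of the target.
    for _ in range(40000):
        if frac >= target_fraction:
            break
        cy = rng.uniform((lo_r + 0.5) / h, (hi_r + 0.5) / h)
        cx = rng.uniform((lo_c + 0.5) / w, (hi_c + 0.5) / w)
        if not leaf_mask_vnir[min(int(cy * h), h - 1), min(int(cx * w), w - 1)]:
            continue
        base_r = config.blob_radius * radius_scale
        if symptom_code == "MP":
            kind, r = "honeydew", base_r
            # Honeydew pools in large patches: use coarse disks while far
            # from the target so per-tile coverage varies realistically,
            # and fine disks near the target to land within 1 pp.
            if target_fraction - frac > 0.12 and rng.uniform() < 0.25:
                r = base_r * 3.0
        else:
            if rng.uniform() < config.spot_share:
                kind, r = "spot", base_r
            else:
                kind, r = "speck", base_r * 0.5
        disks.append((cy, cx, r, kind))
        r0 = max(0, int((cy - r) * h) - 1)
        r1 = min(h, int((cy + r) * h) + 2)
        c0 = max(0, int((cx - r) * w) - 1)
        c1 = min(w, int((cx + r) * w) + 2)
        yy = (np.arange(r0, r1, dtype=np.float64)[:, None] + 0.5) / h
        xx = (np.arange(c0, c1, dtype=np.float64)[None, :] + 0.5) / w
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        covered[r0:r1, c0:c1] |= inside & leaf_mask_vnir[r0:r1, c0:c1]
        frac = covered.sum() / leaf_px
    _paint_disks(type_map_vnir, disks,
                 lambda k: {"honeydew": T_HONEYDEW, "spot": T_SPOT,
                            "speck": T_SPECK}[k])
    return disks


_CODE_OF = {"honeydew": T_HONEYDEW, "spot": T_SPOT, "speck": T_SPECK}


def _white_patch_region(dims) -> tuple[int, int, int, int]:
    h, w = dims
    return (0, max(2, round(0.10 * h)), 0, max(2, round(0.16 * w)))


def _illuminant(spec: CameraSpec) -> np.ndarray:
    """Smooth halogen-like lamp spectrum (arbitrary positive units)."""
    wl = spec.wavelengths
    return 0.4 + 0.6 * np.exp(-0.5 * ((wl - 1100.0) / 900.0) ** 2)


def _render_cube(type_map: np.ndarray, spec: CameraSpec,
                 config: SceneConfig, rng: np.random.Generator,
                 scene_id: str) -> SpectralCube:
    """Turn a pixel-type map into a raw radiance cube: reflectance lookup,
    per-pixel Gaussian noise, lateral illumination gradient, lamp spectrum,
    optional additive ambient light."""
    lut = config.params.spectra_lut(spec).astype(np.float32)
    refl = lut[type_map]
    if config.noise_sd > 0:
        refl = refl + rng.normal(
            0.0, config.noise_sd, size=refl.shape).astype(np.float32)
        np.clip(refl, 0.0, None, out=refl)
    h, w = type_map.shape
    field_1d = 1.0 + config.illumination_amplitude * np.linspace(-1.0, 1.0, w)
    illum = _illuminant(spec).astype(np.float32)
    raw = refl * illum[None, None, :] * field_1d.astype(np.float32)[None, :, None]
    if config.ambient_amplitude > 0:
        # Daylight-ish ambient: stronger toward the visible end.
        wl = spec.wavelengths
        ambient = config.ambient_amplitude * (
            0.3 + 0.7 * np.exp(-0.5 * ((wl - 550.0) / 600.0) ** 2))
        amb_field = 1.0 + 0.3 * np.sin(
            np.linspace(0.0, np.pi, w))  # brighter mid-row
        raw = raw + (ambient.astype(np.float32)[None, None, :]
                     * amb_field.astype(np.float32)[None, :, None])
    return SpectralCube(values=raw, spec=spec, calibrated=False,
                        scene_id=scene_id, class_label=config.class_label)


def _sample_coverage(rng, mean: float, sd: float) -> float:
    """Truncated-normal coverage via rejection; exact mean when sd == 0."""
    if sd <= 0.0:
        return float(np.clip(mean, 0.0, 1.0))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if 0.0 <= x <= 1.0:
            return float(x)
    return float(np.clip(mean, 0.0, 1.0))


def _sample_insects(rng, class_label: str, coverage: float) -> int:
    """Per-scene insect count coupled to realized symptom coverage."""
    mean, _sd = MEAN_INSECTS[class_label]
    cov_mean = COVERAGE[class_label][0]
    if mean == 0.0 or cov_mean == 0.0:
        return 0
    lam = mean * coverage / cov_mean
    return int(rng.poisson(lam))


def _build_leaf_maps(rng, config: SceneConfig, dims_v, dims_s,
                     n_leaves: int, with_stem: bool,
                     class_label: str, scale: float = 1.0):
    """Shared renderer: stem (optional) plus ``n_leaves`` ellipses with
    independently sampled symptom coverage, painted in order so later leaves
    occlude earlier ones.  Returns (type_map_vnir, type_map_swir,
    realized symptom fraction of visible leaf area)."""
    tm_v = np.full(dims_v, T_BG, dtype=np.uint8)
    tm_s = np.full(dims_s, T_BG, dtype=np.uint8)
    wr_v = _white_patch_region(dims_v)
    wr_s = _white_patch_region(dims_s)
    tm_v[wr_v[0]:wr_v[1], wr_v[2]:wr_v[3]] = T_WHITE
    tm_s[wr_s[0]:wr_s[1], wr_s[2]:wr_s[3]] = T_WHITE

    shapes = []  # (kind, geometry) in paint order
    if with_stem:
        shapes.append(("stem", (0.30, 0.52, 0.68, 0.022)))
    # A dissected leaf is arranged to fill most of the frame; plant-tier
    # leaves are smaller and overlap.
    single = n_leaves == 1 and not with_stem
    if single:
        base_ry, base_rx = 0.38, 0.27
    else:
        base_ry, base_rx = 0.17, 0.115
    for _ in range(n_leaves):
        s = scale * rng.uniform(0.85, 1.05 if single else 1.15)
        ry, rx = base_ry * s, base_rx * s
        if ry >= 0.44:
            raise ConfigError("leaf does not fit scene dimensions")
        if single:
            cy, cx = 0.55, 0.55
            angle = rng.uniform(0.0, np.pi)
        else:
            cy = rng.uniform(0.28, 0.80)
            cx = rng.uniform(0.30, 0.78)
            angle = rng.uniform(0.0, np.pi)
        shapes.append(("leaf", (cy, cx, ry, rx, angle)))

    mean_cov, sd_cov = config.coverage
    leaf_index = 0
    for kind, geom in shapes:
        if kind == "stem":
            y0, x0, length, half_w = geom
            yy, xx = _grid(dims_v)
            stem_v = ((np.abs(xx - x0) <= half_w) & (yy >= y0)
                      & (yy <= y0 + length))
            tm_v[stem_v & (tm_v != T_WHITE)] = T_STEM
            yy, xx = _grid(dims_s)
            stem_s = ((np.abs(xx - x0) <= half_w) & (yy >= y0)
                      & (yy <= y0 + length))
            tm_s[stem_s & (tm_s != T_WHITE)] = T_STEM
            continue
        cy, cx, ry, rx, angle = geom
        leaf_v = _ellipse(dims_v, cy, cx, ry, rx, angle)
        leaf_v &= tm_v != T_WHITE
        tm_v[leaf_v] = T_LEAF
        leaf_s = _ellipse(dims_s, cy, cx, ry, rx, angle)
        leaf_s &= tm_s != T_WHITE
        tm_s[leaf_s] = T_LEAF
        if class_label != "UC":
            target = _sample_coverage(rng, mean_cov, sd_cov)
            if n_leaves > 1:
                # Canopy gradient: colonies establish on older foliage and
                # honeydew accumulates below them, so the later-painted
                # (topmost, least occluded) leaves carry fewer symptoms.
                # The visible symptomatic fraction of a plant is therefore
                # lower than that of a dissected-leaf image on average.
                target *= 1.0 - 0.15 * leaf_index / max(1, n_leaves - 1)
            # Per-disk (or per-gap) area increments stay under 1 pp of the
            # leaf area, so realized coverage lands within 1 pp of target.
            if class_label == "MP" and target > 0.5:
                gaps = _carve_gaps(rng, leaf_v, tm_v, target, config,
                                   radius_scale=ry / 0.30)
                _replay_gaps(tm_s, leaf_s, gaps)
            else:
                disks = _grow_symptoms(rng, leaf_v, tm_v, target, config,
                                       class_label, radius_scale=ry / 0.30)
                _paint_disks(tm_s, disks, _CODE_OF.__getitem__)
        leaf_index += 1

    symptomatic = np.isin(tm_v, (T_HONEYDEW, T_SPOT, T_SPECK))
    leafy = symptomatic | (tm_v == T_LEAF)
    frac = float(symptomatic.sum() / leafy.sum()) if leafy.any() else 0.0
    return tm_v, tm_s, frac


def _white_bbox(tm: np.ndarray) -> tuple[int, int, int, int]:
    rows, cols = np.nonzero(tm == T_WHITE)
    return (int(rows.min()), int(rows.max()) + 1,
            int(cols.min()), int(cols.max()) + 1)


def _finish_scene(config, rng, tm_v, tm_s, frac, scene_id,
                  spans=None, plant_meta=None) -> Scene:
    vnir = _render_cube(tm_v, VNIR, config, rng, scene_id)
    swir = _render_cube(tm_s, SWIR, config, rng, scene_id)
    leaf_codes = (T_LEAF, T_HONEYDEW, T_SPOT, T_SPECK)
    count = _sample_insects(rng, config.class_label, frac)
    scene = Scene(
        scene_id=scene_id, class_label=config.class_label, tier=config.tier,
        vnir=vnir, swir=swir,
        truth_mask_vnir=np.isin(tm_v, leaf_codes),
        truth_mask_swir=np.isin(tm_s, leaf_codes),
        symptom_map_vnir=tm_v, symptom_map_swir=tm_s,
        white_region_vnir=_white_bbox(tm_v),
        white_region_swir=_white_bbox(tm_s),
        symptom_fraction=frac, insect_count=count, plant_spans=spans)
    if plant_meta is not None:
        scene.plant_labels, scene.plant_fractions, scene.plant_counts = plant_meta
    return scene


def generate_leaf_scene(config: SceneConfig, scene_id: str = "leaf") -> Scene:
    """Single dissected leaf on a dark background with a white patch."""
    if config.tier != "leaf":
        raise ConfigError("generate_leaf_scene requires tier == 'leaf'")
    rng = np.random.default_rng(config.seed)
    tm_v, tm_s, frac = _build_leaf_maps(
        rng, config, config.vnir_dims, config.swir_dims,
        n_leaves=1, with_stem=False, class_label=config.class_label)
    return _finish_scene(config, rng, tm_v, tm_s, frac, scene_id)


def generate_plant_scene(config: SceneConfig, scene_id: str = "plant") -> Scene:
    """Whole potted plant: overlapping leaves around a stem; symptomatic
    area may be occluded by later-painted leaves."""
    if config.tier != "plant":
        raise ConfigError("generate_plant_scene requires tier == 'plant'")
    rng = np.random.default_rng(config.seed)
    tm_v, tm_s, frac = _build_leaf_maps(
        rng, config, config.vnir_dims, config.swir_dims,
        n_leaves=config.n_leaves, with_stem=True,
        class_label=config.class_label)
    return _finish_scene(config, rng, tm_v, tm_s, frac, scene_id)


def generate_greenhouse_scene(config: SceneConfig,
                              scene_id: str = "row") -> Scene:
    """One image per greenhouse row: several plants side by side, with axial
    compression, per-plant scale jitter and additive ambient light.  Returns
    horizontal pixel spans (VNIR resolution) per plant."""
    if config.tier != "greenhouse":
        raise ConfigError("generate_greenhouse_scene requires tier 'greenhouse'")
    rng = np.random.default_rng(config.seed)
    num, den = VNIR_SWIR_RATIO
    ph_s, pw_s = config.swir_dims            # per-plant SWIR dims
    ph_v, pw_v = ph_s * num // den, pw_s * num // den
    strip_s = den                             # white strip: one SWIR tile wide
    strip_v = num
    tiles_v = [np.full((ph_v, strip_v), T_BG, dtype=np.uint8)]
    tiles_s = [np.full((ph_s, strip_s), T_BG, dtype=np.uint8)]
    wr_v = _white_patch_region((ph_v, strip_v))
    wr_s = _white_patch_region((ph_s, strip_s))
    tiles_v[0][wr_v[0]:wr_v[1], wr_v[2]:wr_v[3]] = T_WHITE
    tiles_s[0][wr_s[0]:wr_s[1], wr_s[2]:wr_s[3]] = T_WHITE

    labels, fracs, counts, spans = [], [], [], []
    offset_v = strip_v
    for p in range(config.n_plants):
        scale = 1.0 + rng.uniform(-config.scale_jitter, config.scale_jitter)
        label = config.class_label
        plant_cfg = dataclasses.replace(config, tier="plant")
        tm_v, tm_s, frac = _build_leaf_maps(
            rng, plant_cfg, (ph_v, pw_v), (ph_s, pw_s),
            n_leaves=config.n_leaves, with_stem=True,
            class_label=label, scale=scale)
        # White patch belongs to the row strip, not to individual plants.
        tm_v[tm_v == T_WHITE] = T_BG
        tm_s[tm_s == T_WHITE] = T_BG
        if (label != "MP"
                and rng.uniform() < config.secondary_infestation_fraction):
            # Unintended aphid presence: mild honeydew on UC/FO plants.
            leaf_v = tm_v == T_LEAF
            target = _sample_coverage(rng, 0.2, 0.1)
            disks = _grow_symptoms(rng, leaf_v, tm_v, target, config, "MP")
            _paint_disks(tm_s, disks, _CODE_OF.__getitem__)
            symptomatic = np.isin(tm_v, (T_HONEYDEW, T_SPOT, T_SPECK))
            leafy = symptomatic | (tm_v == T_LEAF)
            frac = float(symptomatic.sum() / max(1, leafy.sum()))
        tiles_v.append(tm_v)
        tiles_s.append(tm_s)
        labels.append(label)
        fracs.append(frac)
        counts.append(_sample_insects(rng, label, frac))
        spans.append((offset_v, offset_v + pw_v))
        offset_v += pw_v

    tm_v = np.hstack(tiles_v)
    tm_s = np.hstack(tiles_s)
    f = config.axial_compression
    if f != 1.0:
        # Line-scan speed mismatch: resample the scan axis (columns).
        new_wv = max(1, round(tm_v.shape[1] * f))
        new_ws = max(1, round(tm_s.shape[1] * f))
        cols_v = np.minimum((np.arange(new_wv) / f).astype(int),
                            tm_v.shape[1] - 1)
        cols_s = np.minimum((np.arange(new_ws) / f).astype(int),
                            tm_s.shape[1] - 1)
        tm_v = tm_v[:, cols_v]
        tm_s = tm_s[:, cols_s]
        spans = [(int(round(a * f)), int(round(b * f))) for a, b in spans]
    symptomatic = np.isin(tm_v, (T_HONEYDEW, T_SPOT, T_SPECK))
    leafy = symptomatic | (tm_v == T_LEAF)
    frac = float(symptomatic.sum() / max(1, leafy.sum()))
    return _finish_scene(config, rng, tm_v, tm_s, frac, scene_id,
                         spans=spans, plant_meta=(labels, fracs, counts))


def generate_scene(config: SceneConfig, scene_id: str | None = None) -> Scene:
    """Dispatch on the configured tier."""
    fn = {"leaf": generate_leaf_scene, "plant": generate_plant_scene,
          "greenhouse": generate_greenhouse_scene}[config.tier]
    return fn(config, scene_id or config.tier)


def dataset_configs(n_per_class: int, tier: str, seed: int,
                    base: SceneConfig | None = None
                    ) -> list[tuple[str, SceneConfig]]:
    """Balanced, deterministic per-scene configs: ``n_per_class`` scenes for
    each of UC, MP, FO.  Per-scene seeds are derived from the global seed so
    any single scene can be regenerated in isolation."""
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    base = base or SceneConfig(tier=tier)
    root = np.random.SeedSequence(seed)
    children = root.spawn(3 * n_per_class)
    out = []
    k = 0
    for label in CLASS_LABELS:
        for i in range(n_per_class):
            scene_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            cfg = dataclasses.replace(base, class_label=label, tier=tier,
                                      seed=scene_seed)
            out.append((f"{tier}_{label}_{i:03d}", cfg))
    return out


def generate_dataset(n_per_class: int, tier: str, seed: int,
                     out_dir: str | Path,
                     base: SceneConfig | None = None) -> pd.DataFrame:
    """Generate a balanced dataset on disk and return its manifest.

    Writes, per scene, the paired ENVI-style cubes and the truth mask (PNG),
    plus ``manifest.csv`` with scene id, tier, class, file paths, realized
    symptom fraction, insect count and scene seed.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for scene_id, cfg in dataset_configs(n_per_class, tier, seed, base):
        scene = generate_scene(cfg, scene_id)
        vnir_path = out_dir / f"{scene_id}_vnir.hdr"
        swir_path = out_dir / f"{scene_id}_swir.hdr"
        mask_path = out_dir / f"{scene_id}_mask.png"
        write_cube(scene.vnir, vnir_path)
        write_cube(scene.swir, swir_path)
        iio.imwrite(mask_path,
                    (scene.truth_mask_vnir * np.uint8(255)))
        row = {
            "scene_id": scene_id, "tier": tier, "class": cfg.class_label,
            "vnir_path": str(vnir_path), "swir_path": str(swir_path),
            "mask_path": str(mask_path),
            "symptom_fraction": scene.symptom_fraction,
            "insect_count": scene.insect_count, "seed": cfg.seed,
            "white_region_vnir": ":".join(map(str, scene.white_region_vnir)),
            "white_region_swir": ":".join(map(str, scene.white_region_swir)),
        }
        if scene.plant_spans is not None:
            row["plant_spans"] = ";".join(f"{a}-{b}"
                                          for a, b in scene.plant_spans)
            row["plant_counts"] = ";".join(map(str, scene.plant_counts))
            row["plant_labels"] = ";".join(scene.plant_labels)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
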