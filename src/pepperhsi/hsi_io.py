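"""Hyperspectral cube data model, ENVI-style I/O and white-reference calibration.

The pipeline works on paired line-scan cubes from two cameras: a VNIR unit
covering 404-994 nm in 184 bands and a SWIR unit covering 954-2511 nm in 288
bands.  Wavelengths are mapped linearly between the endpoint wavelengths of
each camera; band indices are 1-based throughout, matching the convention of
instrument software.  Radiance cubes are converted to relative reflectance by
dividing every pixel spectrum by the per-band mean signal of an in-scene white
reference plate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "CameraSpec",
    "SpectralCube",
    "WhiteReference",
    "VNIR",
    "SWIR",
    "CLASS_LABELS",
    "band_wavelength",
    "nearest_band",
    "calibrate_reflectance",
    "read_cube",
    "write_cube",
    "compose_visualization",
    "CalibrationError",
    "FormatError",
]

#: Class labels: uninfested control, Myzus persicae, Frankliniella occidentalis.
#: UC first so that probability ties resolve conservatively (do not alarm).
CLASS_LABELS = ("UC", "MP", "FO")

#: Reflectance ceiling after calibration.  Specular glint (e.g. on honeydew)
#: can exceed the white plate slightly; values are clamped here rather than
#: left unbounded.
REFLECTANCE_CLIP = 1.2


class CalibrationError(ValueError):
    """Raised when white-reference calibration is impossible."""


class FormatError(ValueError):
    """Raised when a cube file is inconsistent with its header."""


@dataclass(frozen=True)
class CameraSpec:
    """Spectral geometry of one line-scan camera.

    The wavelength grid is linear between ``wl_min`` and ``wl_max`` with
    ``n_bands`` samples; the nominal ``spectral_resolution`` is descriptive
    only and does not define the grid step.
    """

    name: str
    n_bands: int
    wl_min: float
    wl_max: float
    spectral_resolution: float
    spatial_width: int

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be < wl_max")

    @property
    def wavelengths(self) -> np.ndarray:
        """Full wavelength grid in nm (length ``n_bands``, strictly increasing)."""
        return np.linspace(self.wl_min, self.wl_max, self.n_bands)


#: The two study cameras.
VNIR = CameraSpec("VNIR-1800", n_bands=184, wl_min=404.0, wl_max=994.0,
                  spectral_resolution=3.5, spatial_width=1800)
SWIR = CameraSpec("SWIR-384me", n_bands=288, wl_min=954.0, wl_max=2511.0,
                  spectral_resolution=7.0, spatial_width=384)


@dataclass
class SpectralCube:
    """H x W x B cube of radiance counts or relative reflectance."""

    values: np.ndarray
    spec: CameraSpec
    calibrated: bool = False
    scene_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype not in (np.float32, np.float64):
            self.values = self.values.astype(np.float32)
        if self.values.ndim != 3:
            raise ValueError("cube values must be H x W x B")
        if self.values.shape[2] != self.spec.n_bands:
            raise ValueError(
                f"cube has {self.values.shape[2]} bands, spec declares "
                f"{self.spec.n_bands}"
            )
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def band(self, band_index: int) -> np.ndarray:
        """Single band image by 1-based band index."""
        if not 1 <= band_index <= self.spec.n_bands:
            raise IndexError(f"band index {band_index} out of range")
        return self.values[:, :, band_index - 1]


@dataclass
class WhiteReference:
    """In-scene white plate: a rectangular region and its per-band mean signal.

    ``region`` is (row_start, row_stop, col_start, col_stop), half-open.
    """

    region: tuple[int, int, int, int]
    per_band_mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def from_cube(cls, cube: SpectralCube,
                  region: tuple[int, int, int, int]) -> "WhiteReference":
        r0, r1, c0, c1 = region
        h, w, _ = cube.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"white region {region} outside cube bounds {(h, w)}")
        mean = cube.values[r0:r1, c0:c1, :].mean(axis=(0, 1)).astype(np.float64)
        return cls(region=region, per_band_mean=mean)


def band_wavelength(spec: CameraSpec, band_index: int) -> float:
    """Wavelength in nm of a 1-based band index, on the linear camera grid."""
    if not 1 <= band_index <= spec.n_bands:
        raise IndexError(
            f"band index {band_index} out of range 1..{spec.n_bands}")
    step = (spec.wl_max - spec.wl_min) / (spec.n_bands - 1)
    return spec.wl_min + (band_index - 1) * step


def nearest_band(spec: CameraSpec, wavelength: float) -> int:
    """1-based band index whose center wavelength is closest to ``wavelength``.

    Ties resolve toward the lower band index.  Queries more than one nominal
    resolution step outside the camera range are rejected.
    """
    if not (spec.wl_min - spec.spectral_resolution
            <= wavelength
            <= spec.wl_max + spec.spectral_resolution):
        raise ValueError(
            f"{wavelength} nm outside {spec.name} range "
            f"[{spec.wl_min}, {spec.wl_max}] (+/- resolution)")
    dist = np.abs(spec.wavelengths - wavelength)
    return int(np.argmin(dist)) + 1  # argmin returns first minimum: low-index tie


def calibrate_reflectance(raw: SpectralCube, white: WhiteReference) -> SpectralCube:
    """Convert a radiance cube to relative reflectance.

    Every pixel's band value is divided by the white plate's per-band mean
    signal; the result is clamped to [0, 1.2] to tolerate slight super-white
    specular glint.  The operation is invariant to any global illumination
    scale because the scale cancels in the ratio.
    """
    if raw.calibrated:
        raise CalibrationError("cube is already calibrated")
    mean = np.asarray(white.per_band_mean, dtype=np.float64)
    if mean.shape != (raw.spec.n_bands,):
        raise CalibrationError("white reference band count does not match cube")
    if np.any(mean <= 0):
        raise CalibrationError("white reference has non-positive band means")
    values = raw.values.astype(np.float64) / mean[None, None, :]
    np.clip(values, 0.0, REFLECTANCE_CLIP, out=values)
    return replace(raw, values=values, calibrated=True)


# ---------------------------------------------------------------------------
# ENVI-style I/O: text header (.hdr) + flat little-endian float32 binary,
# band-interleaved-by-line (BIL).


def write_cube(cube: SpectralCube, header_path: str | Path) -> Path:
    """Write a cube as an ENVI-style .hdr / .raw pair; returns the header path."""
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    raw_path = header_path.with_suffix(".raw")
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.6f}" for x in cube.spec.wavelengths)
    header = (
        "ENVI\n"
        f"description = {{{cube.scene_id or 'cube'}}}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bil\n"
        "byte order = 0\n"
        f"camera = {cube.spec.name}\n"
        f"calibrated = {int(cube.calibrated)}\n"
        f"class label = {cube.class_label or 'unknown'}\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    # BIL: line-major, band-middle: (lines, bands, samples)
    np.ascontiguousarray(
        cube.values.transpose(0, 2, 1).astype("<f4")).tofile(raw_path)
    return header_path


_HDR_FIELD = re.compile(r"^\s*([a-z ]+?)\s*=\s*(.*)$", re.IGNORECASE)


def _parse_header(text: str) -> dict[str, str]:
    # Collapse {...} blocks (possibly multi-line) before line parsing.
    text = re.sub(r"\{([^}]*)\}", lambda m: m.group(1).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        m = _HDR_FIELD.match(line)
        if m:
            fields[m.group(1).strip().lower()] = m.group(2).strip()
    return fields


def read_cube(header_path: str | Path) -> SpectralCube:
    """Read an ENVI-style .hdr / .raw pair written by :func:`write_cube`."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"header missing field {exc}") from exc
    if fields.get("interleave", "bil").lower() != "bil":
        raise FormatError(f"unsupported interleave {fields.get('interleave')!r}")
    wl = np.array([float(x) for x in fields["wavelength"].split(",") if x.strip()])
    if wl.size != b:
        raise FormatError(
            f"header declares {b} bands but lists {wl.size} wavelengths")
    raw_path = header_path.with_suffix(".raw")
    data = np.fromfile(raw_path, dtype="<f4")
    if data.size != h * w * b:
        raise FormatError(
            f"file size {data.size} values, header implies {h * w * b}")
    values = data.reshape(h, b, w).transpose(0, 2, 1)
    name = fields.get("camera", "unknown")
    res = {VNIR.name: VNIR.spectral_resolution,
           SWIR.name: SWIR.spectral_resolution}.get(name, float(np.diff(wl).mean()))
    spec = CameraSpec(name=name, n_bands=b, wl_min=float(wl[0]),
                      wl_max=float(wl[-1]), spectral_resolution=res,
                      spatial_width=w)
    label = fields.get("class label", "unknown")
    return SpectralCube(
        values=values, spec=spec,
        calibrated=bool(int(fields.get("calibrated", "0"))),
        scene_id=fields.get("description", ""),
        class_label=label if label in CLASS_LABELS else None)


def compose_visualization(cube: SpectralCube,
                          band_triplet: tuple[int, int, int]) -> np.ndarray:
    """Three-band false-color 8-bit image for inspection and annotation.

    Each channel is the selected band min-max stretched to [0, 255]; a
    constant band maps to an all-zero channel.  The study used bands
    (20, 120, 180) of each camera for its segmentation-annotation images.
    """
    channels = []
    for idx in band_triplet:
        band = cube.band(idx).astype(np.float64)
        lo, hi = band.min(), band.max()
        if hi > lo:
            ch = (band - lo) / (hi - lo) * 255.0
        else:
            ch = np.zeros_like(band)
        channels.append(np.round(ch).astype(np.uint8))
    return np.stack(channels, axis=-1)
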