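"""Hyperspectral cube I/O, calibration, and basic raster utilities.

A hypercube is an ``H x W x C`` raster bound to a wavelength grid. Raw sensor
counts are converted to relative reflectance with dark-current and
white-reference frames using the flat-field convention

    R = (raw - dark) / (white - dark)

computed per band. Cubes and masks are stored on disk in the ENVI dialect
(a plain-text ``.hdr`` plus a raw binary raster), with per-specimen metadata
in a YAML sidecar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "CalibrationFrames",
    "RGBComposite",
    "SceneMeta",
    "SpecimenScene",
    "ConfigurationError",
    "FormatError",
    "build_band_grid",
    "calibrate",
    "make_rgb",
    "trim_tissue_edge",
    "read_envi",
    "write_envi",
    "read_scene",
    "write_scene",
]

SPECIMEN_TYPES = ("T", "N", "TN")
COHORTS = ("conventional", "hpv_pos")
MODALITIES = ("reflectance", "autofluorescence", "nbdg", "proflavin", "rgb")

#: mask raster codes
BACKGROUND, NORMAL, TUMOR = 0, 1, 2

#: default spatial scale of the imaging system (µm per pixel)
DEFAULT_RESOLUTION_UM = 25.0


class ConfigurationError(ValueError):
    """Raised for invalid grid/parameter configurations."""


class FormatError(ValueError):
    """Raised for malformed or inconsistent on-disk rasters."""


# ---------------------------------------------------------------------------
# Wavelength grids and cubes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform band grid from ``start_nm`` to ``stop_nm`` inclusive."""

    start_nm: float
    stop_nm: float
    step_nm: float
    bands: np.ndarray = field(repr=False)

    @property
    def C(self) -> int:
        return len(self.bands)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.bands - wavelength_nm)))

    def __eq__(self, other) -> bool:  # bands array breaks default eq
        return (
            isinstance(other, WavelengthGrid)
            and self.start_nm == other.start_nm
            and self.stop_nm == other.stop_nm
            and self.step_nm == other.step_nm
            and np.array_equal(self.bands, other.bands)
        )


def build_band_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build the uniform wavelength grid of a band-sequential acquisition.

    The instrument steps through bands of width ``step_nm`` from ``start_nm``
    to ``stop_nm`` inclusive, giving ``C = (stop - start)/step + 1`` bands
    (e.g. 450-900 nm at 5 nm -> 91 bands; 500-720 nm at 10 nm -> 23 bands).
    """
    if step_nm <= 0:
        raise ConfigurationError(f"step must be positive, got {step_nm}")
    if start_nm > stop_nm:
        raise ConfigurationError(f"start {start_nm} exceeds stop {stop_nm}")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError(
            f"step {step_nm} does not divide the range ({start_nm}, {stop_nm}) exactly"
        )
    n = int(round(n_steps)) + 1
    bands = start_nm + step_nm * np.arange(n, dtype=float)
    bands[-1] = stop_nm  # exact endpoints despite float accumulation
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm), bands)


@dataclass
class Hypercube:
    """Calibrated (reflectance) or raw (counts) ``H x W x C`` raster."""

    values: np.ndarray
    grid: WavelengthGrid
    resolution_um_per_px: float = DEFAULT_RESOLUTION_UM

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise FormatError(f"cube must be H x W x C, got shape {self.values.shape}")
        if self.values.shape[2] != self.grid.C:
            raise FormatError(
                f"cube has {self.values.shape[2]} bands but grid lists {self.grid.C}"
            )
        if self.resolution_um_per_px <= 0:
            raise ConfigurationError("resolution must be positive")

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class CalibrationFrames:
    """Dark-current and white-reference frames (raw counts)."""

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self) -> None:
        if self.dark.shape != self.white.shape:
            raise FormatError(
                f"dark {self.dark.shape} and white {self.white.shape} shapes differ"
            )


def calibrate(
    raw: Hypercube,
    frames: CalibrationFrames,
    *,
    denominator: str = "white_minus_dark",
    clip: bool = False,
) -> tuple[Hypercube, np.ndarray]:
    """Flat-field a raw cube to relative reflectance, band by band.

    Each band is normalized as ``(raw - dark) / (white - dark)`` (or
    ``(raw - dark) / white`` with ``denominator="white"``, for instruments
    whose white normalization was not dark-subtracted). Reflectance above 1
    (specular glare) is retained unless ``clip=True``; clipping is intended
    for visualization only, since glare pixels stay in the analysis.

    Returns
    -------
    (reflectance, flagged)
        ``flagged`` is a boolean ``H x W x C`` array marking elements whose
        denominator was not strictly positive; those elements are set to 0
        rather than silently propagating NaN/inf.
    """
    if frames.dark.shape != raw.values.shape:
        raise FormatError(
            f"calibration frames {frames.dark.shape} do not match cube {raw.values.shape}"
        )
    if denominator == "white_minus_dark":
        denom = frames.white - frames.dark
    elif denominator == "white":
        denom = np.asarray(frames.white, dtype=float)
    else:
        raise ConfigurationError(f"unknown denominator convention {denominator!r}")
    flagged = denom <= 0
    safe = np.where(flagged, 1.0, denom)
    refl = (raw.values - frames.dark) / safe
    refl[flagged] = 0.0
    if clip:
        refl = np.clip(refl, 0.0, 1.0)
    return Hypercube(refl, raw.grid, raw.resolution_um_per_px), flagged


# ---------------------------------------------------------------------------
# RGB composites
# ---------------------------------------------------------------------------

#: canonical R/G/B kernel centers within a 450-900 nm grid
DEFAULT_RGB_CENTERS_NM = (650.0, 550.0, 450.0)
DEFAULT_RGB_SIGMA_NM = 30.0


@dataclass
class RGBComposite:
    values: np.ndarray  # H x W x 3
    kernel_centers_nm: tuple
    kernel_sigmas_nm: tuple


def _gaussian_band_weights(grid: WavelengthGrid, center: float, sigma: float) -> np.ndarray:
    if not (grid.start_nm <= center <= grid.stop_nm):
        raise ConfigurationError(
            f"kernel center {center} nm outside grid range "
            f"[{grid.start_nm}, {grid.stop_nm}] nm"
        )
    if sigma <= 0:  # delta-kernel limit: the single nearest band
        w = np.zeros(grid.C)
        w[grid.index_of(center)] = 1.0
        return w
    w = np.exp(-((grid.bands - center) ** 2) / (2.0 * sigma**2))
    return w / w.sum()


def make_rgb(
    cube: Hypercube,
    centers_nm=DEFAULT_RGB_CENTERS_NM,
    sigmas_nm=(DEFAULT_RGB_SIGMA_NM,) * 3,
) -> RGBComposite:
    """Collapse a calibrated cube to an RGB composite with Gaussian kernels.

    Each channel is a convex combination of bands: weights proportional to a
    Gaussian centered on the channel's wavelength, normalized to sum to one.
    """
    if len(centers_nm) != 3 or len(sigmas_nm) != 3:
        raise ConfigurationError("exactly three kernel centers and sigmas required")
    channels = []
    for center, sigma in zip(centers_nm, sigmas_nm):
        w = _gaussian_band_weights(cube.grid, center, sigma)
        channels.append(np.tensordot(cube.values, w, axes=([2], [0])))
    rgb = np.stack(channels, axis=-1)
    return RGBComposite(rgb, tuple(centers_nm), tuple(sigmas_nm))


# ---------------------------------------------------------------------------
# Tissue-edge trimming
# ---------------------------------------------------------------------------


def trim_tissue_edge(tissue_mask: np.ndarray, n_pixels: int) -> np.ndarray:
    """Erode ``n_pixels`` from the tissue boundary (square structuring element).

    The free edge of a flattened specimen is too thin for a reliable signal,
    so the outer rim (10 px = 0.25 mm at 25 µm/px by default elsewhere) is
    discarded from all performance calculations. Chebyshev (square) erosion is
    used so that "n pixels at the edge" is exact along rows, columns, and
    diagonals alike.
    """
    if n_pixels < 0:
        raise ConfigurationError("n_pixels must be nonnegative")
    mask = np.asarray(tissue_mask, dtype=bool)
    if n_pixels == 0:
        return mask.copy()
    size = 2 * n_pixels + 1
    eroded = ndimage.binary_erosion(mask, structure=np.ones((size, size), bool))
    if mask.any() and not eroded.any():
        warnings.warn(
            f"edge trim of {n_pixels} px eroded the tissue mask to empty",
            stacklevel=2,
        )
    return eroded


# ---------------------------------------------------------------------------
# ENVI raster I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def write_envi(
    path: str | Path,
    values: np.ndarray,
    wavelengths: np.ndarray | None = None,
    interleave: str = "bsq",
) -> None:
    """Write an ``H x W x C`` (or ``H x W``) array as an ENVI raster.

    ``path`` is the header path (``.hdr``); the raster goes to the matching
    ``.img`` file. Little-endian byte order.
    """
    path = Path(path)
    if path.suffix != ".hdr":
        path = path.with_suffix(".hdr")
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[:, :, None]
    if values.ndim != 3:
        raise FormatError(f"expected 2-D or 3-D raster, got shape {values.shape}")
    h, w, c = values.shape
    if wavelengths is not None and len(wavelengths) != c:
        raise FormatError(f"{len(wavelengths)} wavelengths listed for {c} bands")
    dtype = np.dtype(values.dtype)
    if dtype not in _ENVI_CODES:
        raise FormatError(f"unsupported dtype {dtype}")
    interleave = interleave.lower()
    if interleave == "bsq":
        ordered = np.transpose(values, (2, 0, 1))
    elif interleave == "bil":
        ordered = np.transpose(values, (0, 2, 1))
    elif interleave == "bip":
        ordered = values
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    lines = [
        "ENVI",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {c}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{float(v):g}" for v in wavelengths)
        lines.append("wavelength units = nm")
        lines.append(f"wavelength = {{{wl}}}")
    path.write_text("\n".join(lines) + "\n")
    ordered.astype(dtype.newbyteorder("<")).tofile(path.with_suffix(".img"))


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        if key is not None:  # inside a braced multi-line value
            buf += " " + line.strip()
            if "}" in line:
                fields[key] = buf
                key = None
            continue
        if "=" not in line:
            continue
        k, _, v = line.partition("=")
        k, v = k.strip().lower(), v.strip()
        if v.startswith("{") and "}" not in v:
            key, buf = k, v
        else:
            fields[k] = v
    return fields


def read_envi(path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI raster; returns ``(H x W x C values, wavelengths or None)``."""
    path = Path(path)
    if path.suffix != ".hdr":
        path = path.with_suffix(".hdr")
    fields = _parse_envi_header(path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        c = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header {path} missing field {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    flat = np.fromfile(path.with_suffix(".img"), dtype=dtype)
    if flat.size != h * w * c:
        raise FormatError(
            f"raster {path.with_suffix('.img')} has {flat.size} elements, "
            f"header promises {h * w * c}"
        )
    if interleave == "bsq":
        values = flat.reshape(c, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        values = flat.reshape(h, c, w).transpose(0, 2, 1)
    elif interleave == "bip":
        values = flat.reshape(h, w, c)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    wavelengths = None
    if "wavelength" in fields:
        raw = fields["wavelength"].strip().strip("{}")
        wavelengths = np.array([float(v) for v in raw.split(",") if v.strip()])
        if len(wavelengths) != c:
            raise FormatError(
                f"{len(wavelengths)} wavelengths listed for {c} bands in {path}"
            )
    return np.ascontiguousarray(values.astype(values.dtype.newbyteorder("="))), wavelengths


# ---------------------------------------------------------------------------
# Specimen scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneMeta:
    patient_id: str
    specimen_type: str  # T, N, or TN
    cohort: str = "conventional"
    modality: str = "reflectance"

    def __post_init__(self) -> None:
        if self.specimen_type not in SPECIMEN_TYPES:
            raise ConfigurationError(f"specimen_type must be one of {SPECIMEN_TYPES}")
        if self.cohort not in COHORTS:
            raise ConfigurationError(f"cohort must be one of {COHORTS}")
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"modality must be one of {MODALITIES}")


@dataclass
class SpecimenScene:
    """One specimen: raw cube, calibration frames, ground truth, metadata."""

    raw: Hypercube
    frames: CalibrationFrames
    gt_mask: np.ndarray  # 0 background, 1 normal, 2 tumor
    meta: SceneMeta
    reflectance: Hypercube | None = None  # cached calibration result

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.gt_mask > BACKGROUND

    def calibrated(self, **kwargs) -> Hypercube:
        if self.reflectance is None or kwargs:
            cube, _ = calibrate(self.raw, self.frames, **kwargs)
            if kwargs:
                return cube
            self.reflectance = cube
        return self.reflectance


def write_scene(scene: SpecimenScene, directory: str | Path) -> Path:
    """Write a scene as ENVI rasters plus a YAML metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    wl = scene.raw.grid.bands
    write_envi(directory / "raw.hdr", scene.raw.values, wl)
    write_envi(directory / "dark.hdr", scene.frames.dark, wl)
    write_envi(directory / "white.hdr", scene.frames.white, wl)
    write_envi(directory / "mask.hdr", scene.gt_mask.astype(np.uint8))
    meta = {
        "patient_id": scene.meta.patient_id,
        "specimen_type": scene.meta.specimen_type,
        "cohort": scene.meta.cohort,
        "modality": scene.meta.modality,
        "resolution_um_per_px": float(scene.raw.resolution_um_per_px),
        "grid": {
            "start_nm": scene.raw.grid.start_nm,
            "stop_nm": scene.raw.grid.stop_nm,
            "step_nm": scene.raw.grid.step_nm,
        },
    }
    (directory / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return directory


def read_scene(directory: str | Path) -> SpecimenScene:
    """Read a scene written by :func:`write_scene` (lossless round trip)."""
    directory = Path(directory)
    meta_raw = yaml.safe_load((directory / "meta.yaml").read_text())
    grid = build_band_grid(**meta_raw["grid"])
    values, wl = read_envi(directory / "raw.hdr")
    if wl is not None and not np.allclose(wl, grid.bands):
        raise FormatError(
            f"wavelengths in {directory}/raw.hdr disagree with metadata grid"
        )
    res = float(meta_raw.get("resolution_um_per_px", DEFAULT_RESOLUTION_UM))
    raw = Hypercube(values, grid, res)
    dark, _ = read_envi(directory / "dark.hdr")
    white, _ = read_envi(directory / "white.hdr")
    mask, _ = read_envi(directory / "mask.hdr")
    meta = SceneMeta(
        patient_id=str(meta_raw["patient_id"]),
        specimen_type=meta_raw["specimen_type"],
        cohort=meta_raw.get("cohort", "conventional"),
        modality=meta_raw.get("modality", "reflectance"),
    )
    return SpecimenScene(raw, CalibrationFrames(dark, white), mask[:, :, 0], meta)
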