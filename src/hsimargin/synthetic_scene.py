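"""Synthetic tissue-phantom generator.

Produces per-patient specimen triplets — primary tumor (T), all-normal (N),
and tumor-involved margin (TN) — as raw hypercubes with matching calibration
frames and exact ground-truth masks, so that the whole margin-detection
pipeline can be exercised and validated without patient data.

The spectral model is phenomenological: smooth class baselines with Gaussian
absorption dips (oxygenated-hemoglobin features at 560/565 nm, deeper in
carcinoma) and a class-dependent near-infrared contrast (normal tissue,
richer in fat/collagen/water, absorbs more above 700 nm). Fluorescence-grid
phantoms reuse the machinery with emission peaks instead of dips. The knob
``class_separation`` scales the SCC-minus-normal mean difference; at zero the
classes are identical and every classifier must fall to chance.

Raw counts are synthesized as ``reflectance * (white - dark) + dark + noise``
so that flat-field calibration recovers the generating reflectance field up
to sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .hypercube_io import (
    BACKGROUND,
    NORMAL,
    TUMOR,
    CalibrationFrames,
    ConfigurationError,
    Hypercube,
    SceneMeta,
    SpecimenScene,
    WavelengthGrid,
    build_band_grid,
    write_scene,
)

__all__ = [
    "SpectralModel",
    "SceneSpec",
    "class_spectrum",
    "generate_patient",
    "generate_cohort",
    "reflectance_grid",
    "fluorescence_grid",
]


def reflectance_grid() -> WavelengthGrid:
    """450-900 nm in 5 nm steps (91 bands)."""
    return build_band_grid(450, 900, 5)


def fluorescence_grid() -> WavelengthGrid:
    """500-720 nm in 10 nm steps (23 bands)."""
    return build_band_grid(500, 720, 10)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _gauss(x, center, width):
    return np.exp(-((x - center) ** 2) / (2.0 * width**2))


@dataclass(frozen=True)
class SpectralModel:
    """Class-conditional spectrum model for the phantom tissue.

    ``noise_sd`` is the additive sensor noise in reflectance units (applied to
    raw counts scaled by the dynamic range). ``pixel_variation_sd`` is a
    per-pixel multiplicative lognormal sigma emulating tissue heterogeneity;
    ``patient_variation_sd`` the analogous per-patient factor. The SCC-minus-
    normal mean difference is floored at ``min_band_margin`` (with the local
    sign) so the classes differ at every band of the grid.
    """

    noise_sd: float = 0.01
    pixel_variation_sd: float = 0.05
    patient_variation_sd: float = 0.03
    min_band_margin: float = 0.04
    hemoglobin_centers_nm: tuple = (560.0, 565.0)
    hemoglobin_width_nm: float = 12.0
    hemoglobin_extra_depth: float = 0.18
    nir_contrast: float = 0.12
    emission_mode: bool = False  # fluorescence phantoms: peaks, not dips

    def baseline(self, bands: np.ndarray) -> np.ndarray:
        if self.emission_mode:
            # broad autofluorescence emission hump
            base = 0.20 + 0.45 * _gauss(bands, 590.0, 70.0)
        else:
            # rising red/NIR reflectance with a broad beta-band Hb depression
            base = (
                0.32
                + 0.28 * _sigmoid((bands - 620.0) / 70.0)
                - 0.10 * _gauss(bands, 545.0, 30.0)
            )
        return np.clip(base, 0.05, 1.45)

    def class_difference(self, bands: np.ndarray) -> np.ndarray:
        """SCC-minus-normal mean spectrum at unit class separation."""
        if self.emission_mode:
            raw = 0.15 * _gauss(bands, 630.0, 20.0) - 0.10 * _gauss(bands, 540.0, 25.0)
        else:
            dips = sum(
                _gauss(bands, c, self.hemoglobin_width_nm)
                for c in self.hemoglobin_centers_nm
            )
            raw = (
                self.nir_contrast * _sigmoid((bands - 720.0) / 40.0)
                - self.hemoglobin_extra_depth * dips
            )
        sign = np.where(raw >= 0, 1.0, -1.0)
        return sign * np.maximum(np.abs(raw), self.min_band_margin)


def class_spectrum(
    model: SpectralModel,
    tissue_class: str,
    grid: WavelengthGrid,
    class_separation: float = 1.0,
) -> np.ndarray:
    """Mean reflectance (or emission) spectrum of one tissue class.

    The normal class sits on the model baseline; the carcinoma class adds
    ``class_separation`` times the class-difference curve, giving deeper
    560/565 nm hemoglobin dips and higher NIR reflectance than normal.
    """
    if tissue_class not in ("scc", "normal"):
        raise ConfigurationError(f"class must be 'scc' or 'normal', got {tissue_class!r}")
    if class_separation < 0:
        raise ConfigurationError("class_separation must be nonnegative")
    base = model.baseline(grid.bands)
    if tissue_class == "normal":
        return base
    return np.clip(base + class_separation * model.class_difference(grid.bands), 0.02, 1.45)


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, optics and nuisance parameters of a phantom scene.

    Image size defaults to a scaled-down specimen (96 px = 2.4 mm at
    25 µm/px). ``margin_blur_px`` blends the two class spectra across the
    tumor-normal interface (partial-volume ambiguity), which is what makes
    margin-distance stratification informative on phantoms.
    """

    image_size: tuple = (96, 96)
    grid: WavelengthGrid = field(default_factory=reflectance_grid)
    resolution_um_per_px: float = 25.0
    tumor_radius_fraction: float = 0.5
    boundary_roughness: float = 0.15
    margin_blur_px: float = 8.0
    glare_fraction: float = 0.01
    t_normal_fraction: float = 0.05
    class_separation: float = 1.0
    background_reflectance: float = 0.03
    dark_level: float = 100.0
    white_level: float = 3000.0
    model: SpectralModel = field(default_factory=SpectralModel)

    def __post_init__(self) -> None:
        if not (0.0 <= self.glare_fraction <= 0.2):
            raise ConfigurationError("glare_fraction must be in [0, 0.2]")
        if self.class_separation < 0:
            raise ConfigurationError("class_separation must be nonnegative")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _tissue_ellipse(shape, rng) -> np.ndarray:
    h, w = shape
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    ry = rng.uniform(0.38, 0.44) * h
    rx = rng.uniform(0.38, 0.44) * w
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _rough_blob(shape, center, radius, roughness, rng) -> np.ndarray:
    """Disk with a Fourier-perturbed radius (irregular tumor boundary)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    r_mod = np.ones_like(theta)
    for k in (2, 3, 5):
        r_mod += roughness / k * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return np.hypot(dy, dx) <= radius * r_mod


def _signed_distance_to_set(inside: np.ndarray) -> np.ndarray:
    """Positive inside the set, negative outside, in pixels."""
    d_out = ndimage.distance_transform_edt(~inside)
    d_in = ndimage.distance_transform_edt(inside)
    return np.where(inside, d_in, -d_out)


def _tn_geometry(spec: SceneSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Tissue mask and tumor-fraction field for a margin (TN) specimen."""
    tissue = _tissue_ellipse(spec.image_size, rng)
    n_tissue = tissue.sum()
    h, w = spec.image_size
    semiminor = 0.4 * min(h, w)
    for _ in range(10):
        cy = h / 2 + rng.uniform(-0.25, 0.25) * semiminor
        cx = w / 2 + rng.uniform(-0.25, 0.25) * semiminor
        radius = spec.tumor_radius_fraction * semiminor
        blob = _rough_blob(spec.image_size, (cy, cx), radius, spec.boundary_roughness, rng)
        tumor = blob & tissue
        frac = tumor.sum() / max(n_tissue, 1)
        if 0.1 <= frac <= 0.9:
            break
    else:
        raise ConfigurationError(
            "could not place a tumor blob with both classes >= 10% of tissue"
        )
    if spec.margin_blur_px > 0:
        sd = _signed_distance_to_set(tumor)
        tumor_weight = np.clip(0.5 + sd / (2.0 * spec.margin_blur_px), 0.0, 1.0)
    else:
        tumor_weight = tumor.astype(float)
    return tissue, np.where(tissue, tumor_weight, 0.0)


def _t_geometry(spec: SceneSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """Primary-tumor specimen: tumor with a small normal rim (if configured)."""
    tissue = _tissue_ellipse(spec.image_size, rng)
    weight = tissue.astype(float)
    if spec.t_normal_fraction > 0:
        # small normal pocket at the tissue periphery
        ys, xs = np.nonzero(tissue)
        edge_d = ndimage.distance_transform_edt(tissue)
        border = np.argsort(edge_d[ys, xs])[: max(1, len(ys) // 20)]
        i = border[rng.integers(len(border))]
        target_area = spec.t_normal_fraction * tissue.sum()
        radius = np.sqrt(target_area / np.pi)
        pocket = _rough_blob(spec.image_size, (ys[i], xs[i]), radius, 0.1, rng)
        weight[pocket & tissue] = 0.0
        # cap so T specimens stay >= 90% tumor on tissue
        if (weight[tissue] == 0).mean() > 0.10:
            weight = tissue.astype(float)
    return tissue, weight


# ---------------------------------------------------------------------------
# Raster synthesis
# ---------------------------------------------------------------------------


def _calibration_frames(spec: SceneSpec, rng) -> CalibrationFrames:
    h, w = spec.image_size
    c = spec.grid.C
    yy, xx = np.mgrid[0:h, 0:w]
    vignette = 1.0 - 0.15 * (((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2) / 2
    lamp = 0.7 + 0.3 * _sigmoid((spec.grid.bands - 550.0) / 120.0)
    white = spec.white_level * vignette[:, :, None] * lamp[None, None, :]
    dark = spec.dark_level * (1.0 + 0.02 * rng.standard_normal((h, w)))[:, :, None]
    dark = np.broadcast_to(dark, (h, w, c)).copy()
    return CalibrationFrames(dark, white)


def _synthesize_scene(
    spec: SceneSpec,
    tissue: np.ndarray,
    tumor_weight: np.ndarray,
    meta: SceneMeta,
    patient_factor: float,
    rng,
) -> SpecimenScene:
    grid = spec.grid
    scc = class_spectrum(spec.model, "scc", grid, spec.class_separation)
    normal = class_spectrum(spec.model, "normal", grid, spec.class_separation)
    h, w = spec.image_size

    wt = tumor_weight[:, :, None]
    refl = wt * scc[None, None, :] + (1.0 - wt) * normal[None, None, :]
    refl *= patient_factor
    pixel_factor = np.exp(
        spec.model.pixel_variation_sd * rng.standard_normal((h, w))
    )[:, :, None]
    refl = refl * pixel_factor
    refl[~tissue] = spec.background_reflectance

    frames = _calibration_frames(spec, rng)
    dyn = frames.white - frames.dark
    noise = spec.model.noise_sd * dyn * rng.standard_normal(refl.shape)
    raw = refl * dyn + frames.dark + noise
    # a sensor never reads above the white reference unless the surface glares
    raw = np.minimum(raw, frames.white)

    if spec.glare_fraction > 0:
        ys, xs = np.nonzero(tissue)
        n_glare = int(round(spec.glare_fraction * len(ys)))
        if n_glare:
            pick = rng.choice(len(ys), size=n_glare, replace=False)
            factor = rng.uniform(1.02, 1.10, size=n_glare)
            raw[ys[pick], xs[pick], :] = frames.white[ys[pick], xs[pick], :] * factor[:, None]

    gt = np.full(spec.image_size, BACKGROUND, dtype=np.uint8)
    gt[tissue & (tumor_weight >= 0.5)] = TUMOR
    gt[tissue & (tumor_weight < 0.5)] = NORMAL

    cube = Hypercube(raw, grid, spec.resolution_um_per_px)
    return SpecimenScene(cube, frames, gt, meta)


# ---------------------------------------------------------------------------
# Patients and cohorts
# ---------------------------------------------------------------------------


def _scene_rng(master_seed: int, patient_index: int, scene_index: int):
    ss = np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                                spawn_key=(patient_index, scene_index))
    return np.random.default_rng(ss)


def generate_patient(
    spec: SceneSpec,
    patient_id: str,
    seed: int,
    *,
    patient_index: int = 0,
    cohort: str = "conventional",
    modality: str = "reflectance",
) -> dict[str, SpecimenScene]:
    """Generate one patient's T/N/TN specimen triplet, deterministically."""
    rng_patient = _scene_rng(seed, patient_index, 3)
    patient_factor = float(
        np.exp(spec.model.patient_variation_sd * rng_patient.standard_normal())
    )
    scenes: dict[str, SpecimenScene] = {}
    for scene_index, stype in enumerate(("T", "N", "TN")):
        rng = _scene_rng(seed, patient_index, scene_index)
        meta = SceneMeta(patient_id, stype, cohort, modality)
        if stype == "T":
            tissue, weight = _t_geometry(spec, rng)
        elif stype == "N":
            tissue = _tissue_ellipse(spec.image_size, rng)
            weight = np.zeros(spec.image_size)
        else:
            tissue, weight = _tn_geometry(spec, rng)
        scenes[stype] = _synthesize_scene(spec, tissue, weight, meta, patient_factor, rng)
    return scenes


def generate_cohort(
    n_patients: int,
    spec: SceneSpec | None = None,
    seed: int = 0,
    *,
    cohort: str = "conventional",
    modality: str = "reflectance",
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a phantom cohort of patient triplets.

    Returns ``(manifest, scenes)`` where ``scenes[(patient_id, specimen_type)]``
    is the in-memory :class:`SpecimenScene`. If ``out_dir`` is given, scenes
    are also written to disk (one directory per scene) along with a
    ``manifest.csv``.
    """
    if n_patients < 5:
        raise ConfigurationError(
            f"fold experiments need >= 5 patients, got {n_patients}"
        )
    spec = spec or SceneSpec()
    rows = []
    scenes: dict[tuple[str, str], SpecimenScene] = {}
    for i in range(n_patients):
        pid = f"P{i:03d}"
        triple = generate_patient(
            spec, pid, seed, patient_index=i, cohort=cohort, modality=modality
        )
        for stype, scene in triple.items():
            path = ""
            if out_dir is not None:
                path = str(Path(out_dir) / f"{pid}_{stype}")
                write_scene(scene, path)
            rows.append(
                {
                    "patient_id": pid,
                    "specimen_type": stype,
                    "cohort": cohort,
                    "modality": modality,
                    "path": path,
                }
            )
            scenes[(pid, stype)] = scene
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest, scenes
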