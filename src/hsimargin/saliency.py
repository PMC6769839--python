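"""Spectral saliency from class-activated gradients (grad-CAM).

Which wavelengths a trained patch classifier relies on is extracted from the
network's gradients: grad-CAM channel weights at the last convolutional block
give a spatial class-activation map, and a gradient-times-input reduction
onto the spectral axis attributes importance to each band. Profiles are
aggregated over correctly classified patches of the target class and min-max
scaled to [0, 1] (0 low saliency, 1 high).

On phantoms whose class contrast is injected only at chosen bands (e.g. the
560/565 nm oxyhemoglobin dips), the recovered profile should peak at exactly
those bands — the recovery property that validates the reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hypercube_io import ConfigurationError, WavelengthGrid
from .patch_cnn import SpectralInceptionNet

__all__ = [
    "SaliencyProfile",
    "gradcam_spectral",
    "aggregate_profiles",
    "CLASS_INDEX",
]

CLASS_INDEX = {"normal": 0, "scc": 1}


@dataclass
class SaliencyProfile:
    wavelengths: np.ndarray
    saliency: np.ndarray  # per band, scaled to [0, 1]
    target_class: str
    n_patches: int

    def top_bands(self, n: int = 2) -> np.ndarray:
        """Wavelengths of the n most salient bands, most salient first."""
        order = np.argsort(self.saliency)[::-1][:n]
        return self.wavelengths[order]


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi <= lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def gradcam_spectral(
    net: SpectralInceptionNet,
    patches: np.ndarray,
    labels: np.ndarray,
    target_class: str,
    grid: WavelengthGrid,
    *,
    reduction: str = "gradient",
    batch_size: int = 64,
) -> SaliencyProfile:
    """Per-wavelength saliency profile for one class.

    Only patches of the target class that the network classifies correctly
    are used. For each such patch, the grad-CAM map (ReLU of the
    channel-weighted last-block activations, weights = spatially-averaged
    class gradients) gates a per-band attribution, which is summed over space
    to one value per band; per-patch profiles are min-max scaled, averaged,
    and rescaled.

    The band attribution is the class-gradient magnitude at the input
    (``reduction="gradient"``, the default). The ``"gradient_x_input"``
    variant weights the gradient by the raw reflectance, which favors bright
    bands (high-NIR reflectance) over genuinely class-informative ones;
    ``"gradient_x_centered"`` weights by the deviation from the pooled mean
    spectrum instead. Both are kept for sensitivity analysis.
    """
    if target_class not in CLASS_INDEX:
        raise ConfigurationError("target_class must be 'scc' or 'normal'")
    cls = CLASS_INDEX[target_class]
    labels = np.asarray(labels).astype(int)
    if len(labels) != len(patches):
        raise ConfigurationError("one label per patch required")
    if reduction not in ("gradient", "gradient_x_input", "gradient_x_centered"):
        raise ConfigurationError(f"unknown reduction {reduction!r}")
    pred = (net.predict_proba(patches) >= 0.5).astype(int)
    keep = np.nonzero((labels == cls) & (pred == cls))[0]
    if len(keep) == 0:
        raise ConfigurationError(
            f"no correctly classified patches of class {target_class!r}"
        )
    mean_spectrum = np.asarray(patches, dtype=np.float32).mean(axis=(0, 1, 2))

    profiles = []
    zero_flag = False
    for lo in range(0, len(keep), batch_size):
        idx = keep[lo : lo + batch_size]
        X = np.asarray(patches[idx], dtype=np.float32)
        acts, grads, input_grad = net.class_gradients(X, cls)
        alpha = grads.mean(axis=(1, 2))  # m x K channel weights
        cam = np.maximum(np.einsum("mhwk,mk->mhw", acts, alpha), 0.0)
        if reduction == "gradient":
            attribution = np.abs(input_grad)
        elif reduction == "gradient_x_input":
            attribution = np.abs(input_grad * X)
        else:
            attribution = np.abs(input_grad * (X - mean_spectrum))
        for j in range(len(idx)):
            c = cam[j]
            if c.max() > 0:
                gate = c / c.sum()
            else:  # constant-output model: fall back to a uniform gate
                gate = np.full(c.shape, 1.0 / c.size)
            prof = np.einsum("hw,hwc->c", gate, attribution[j])
            if prof.max() <= 0:
                zero_flag = True
                profiles.append(np.zeros(grid.C))
            else:
                profiles.append(_minmax(prof))
    saliency = np.mean(profiles, axis=0)
    if saliency.max() > 0:
        saliency = _minmax(saliency)
    else:
        warnings.warn(
            "all class gradients vanish: saliency profile is identically zero",
            stacklevel=2,
        )
    if zero_flag and saliency.max() > 0:
        warnings.warn("some patches had vanishing gradients", stacklevel=2)
    return SaliencyProfile(
        wavelengths=grid.bands.copy(),
        saliency=saliency,
        target_class=target_class,
        n_patches=int(len(keep)),
    )


def aggregate_profiles(profiles: list) -> SaliencyProfile:
    """Average saliency profiles from independently trained models.

    Genuinely class-informative bands reappear in every model, while
    incidental reference bands differ between trainings, so averaging the
    (already [0, 1]-scaled) profiles and rescaling sharpens the consensus.
    """
    if not profiles:
        raise ConfigurationError("no profiles to aggregate")
    wl = profiles[0].wavelengths
    cls = profiles[0].target_class
    for p in profiles[1:]:
        if not np.array_equal(p.wavelengths, wl) or p.target_class != cls:
            raise ConfigurationError(
                "profiles must share one wavelength grid and target class"
            )
    mean = np.mean([p.saliency for p in profiles], axis=0)
    if mean.max() > 0:
        mean = _minmax(mean)
    return SaliencyProfile(
        wavelengths=wl.copy(),
        saliency=mean,
        target_class=cls,
        n_patches=int(sum(p.n_patches for p in profiles)),
    )
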