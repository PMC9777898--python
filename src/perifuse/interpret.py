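"""Interpretability: Grad-CAM over the encoder's classification path and
2-D PCA projection of the latent space.

Grad-CAM targets the last convolutional activation of the encoder and uses
the severity-head logit as the class score: channel weights are the
spatially averaged gradients of the score, the heatmap is the ReLU of the
weighted activation sum, bilinearly upsampled to the input size and min-max
normalized.  ``localization_score`` turns the qualitative saliency picture
into a number — the fraction of total heat mass falling inside the planted
lesion mask — whose chance baseline is the mask's area fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .autoencoder import TrainedAE, _as_batch
from .images import ImageTensor

__all__ = [
    "SaliencyMap",
    "LatentProjection",
    "grad_cam",
    "localization_score",
    "pca_project",
]


@dataclass
class SaliencyMap:
    """Normalized Grad-CAM heatmap at input resolution."""

    heat: np.ndarray
    subject_id: str = ""
    target_layer: str = "encoder.last_conv_activation"
    all_zero: bool = False


def grad_cam(trained: TrainedAE, image) -> SaliencyMap:
    """Grad-CAM of the severity-head logit w.r.t. the last encoder conv."""
    if isinstance(image, ImageTensor):
        sid = image.subject_id
    else:
        sid = ""
    x = _as_batch([image] if not isinstance(image, np.ndarray) or image.ndim == 2 else image)
    if x.shape[0] != 1:
        raise ValueError("grad_cam expects a single image")
    if x.shape[2:] != trained.image_size:
        raise ValueError(
            f"image has size {x.shape[2:]}, model expects {trained.image_size}"
        )
    target = trained.gradcam_layer
    _, acts = trained.encoder.forward(x, train=False, collect=True)
    activation = acts[target]  # (1, C, h, w)
    z = acts[-1]
    trained.head.forward(z, train=False)
    trained.encoder.zero_grad()
    trained.head.zero_grad()
    # d(logit)/d(latent), then back through the encoder tail to the target
    d_latent = trained.head.backward(np.ones((1, 1)))
    d_act = trained.encoder.backward(d_latent, stop_at=target)

    weights = d_act.mean(axis=(2, 3))  # (1, C): spatially averaged gradients
    cam = np.maximum((weights[:, :, None, None] * activation).sum(axis=1), 0.0)[0]
    h, w = trained.image_size
    cam = ndimage.zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0.0:
        warnings.warn("Grad-CAM produced an all-zero map (zero gradients)")
        return SaliencyMap(heat=np.zeros((h, w)), subject_id=sid, all_zero=True)
    lo = cam.min()
    cam = (cam - lo) / (peak - lo) if peak > lo else np.ones_like(cam)
    return SaliencyMap(heat=cam, subject_id=sid)


def localization_score(saliency, mask) -> float:
    """Fraction of total heat mass inside the mask; chance = area fraction."""
    heat = saliency.heat if isinstance(saliency, SaliencyMap) else np.asarray(saliency, float)
    mask = np.asarray(mask, dtype=bool)
    if heat.shape != mask.shape:
        raise ValueError(f"shape mismatch: heat {heat.shape} vs mask {mask.shape}")
    if not mask.any():
        raise ValueError("empty mask: localization score undefined")
    total = heat.sum()
    if total <= 0.0:
        raise ValueError("all-zero heat map: localization score undefined")
    return float(heat[mask].sum() / total)


@dataclass
class LatentProjection:
    """Top-2 principal-component projection of latent vectors."""

    coords: np.ndarray  # (n, 2)
    explained: tuple[float, float]
    labels: np.ndarray


def pca_project(latents, labels) -> LatentProjection:
    """Mean-centred top-2 PCA with a deterministic sign convention.

    Each component's largest-magnitude loading is made positive so the
    projection does not depend on the eigensolver's sign choices.
    """
    x = np.asarray(latents, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError(f"need an (n>=3, d>=2) latent matrix, got {x.shape}")
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("zero-variance latents cannot be projected")
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(x)
    comps = pca.components_.copy()
    for k in range(2):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] *= -1.0
            coords[:, k] *= -1.0
    ev = pca.explained_variance_ratio_
    return LatentProjection(
        coords=coords,
        explained=(float(ev[0]), float(ev[1])),
        labels=np.asarray(labels),
    )
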