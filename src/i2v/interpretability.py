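"""Grad-CAM attention maps over a chosen convolutional layer.

For a target class v with pre-softmax score y_v and feature maps A^k of a
convolutional layer, each channel weight is the spatial mean of the gradient,

    α_k = (1/F) Σ_ij ∂y_v / ∂A^k_ij,          F = H_l · W_l,

and the map is the rectified weighted channel sum ReLU(Σ_k α_k A^k),
upsampled bilinearly to the input resolution.  The model only needs to expose
``logits_and_activation_grad`` (as the package's CNN does), so analytic stub
models can be attributed the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize


@dataclass
class GradCamMap:
    """Raw heatmap at feature-map resolution plus its upsampled version."""

    heatmap: np.ndarray
    upsampled: np.ndarray
    target_class: int
    layer_name: str

    def normalized(self) -> np.ndarray:
        """Upsampled map min-max scaled to [0, 1] for display."""
        h = self.upsampled
        lo, hi = float(h.min()), float(h.max())
        if hi - lo < 1e-12:
            return np.zeros_like(h)
        return (h - lo) / (hi - lo)


def gradcam(model, image: np.ndarray, target_class: int | None = None,
            layer: str | None = None) -> GradCamMap:
    """Grad-CAM heatmap of ``image`` (H, W, 3 uint8) for ``target_class``.

    ``layer`` defaults to the model's last convolutional layer and
    ``target_class`` to the argmax prediction.  Gradients are taken of the
    pre-softmax logit.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    x = arr.transpose(2, 0, 1).astype(np.float32) / 255.0
    if layer is None:
        layer = model.last_conv_layer
    if target_class is None:
        logits, _, _ = model.logits_and_activation_grad(x, 0, layer)
        target_class = int(np.argmax(logits))
    _, activation, grad = model.logits_and_activation_grad(
        x, int(target_class), layer)
    alphas = grad.mean(axis=(1, 2))                      # (K,)
    raw = np.tensordot(alphas, activation, axes=(0, 0))  # (H_l, W_l)
    heat = np.maximum(raw, 0.0)
    upsampled = resize(heat, arr.shape[:2], order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True)
    return GradCamMap(heatmap=heat, upsampled=np.asarray(upsampled),
                      target_class=int(target_class), layer_name=layer)


def overlay(image: np.ndarray, gmap: GradCamMap, colormap: str = "jet",
            opacity: float = 0.5) -> np.ndarray:
    """Blend the colour-mapped heatmap (red high, blue low) over the image."""
    arr = np.asarray(image)
    if gmap.upsampled.shape != arr.shape[:2]:
        raise ValueError(
            f"heatmap {gmap.upsampled.shape} does not match image {arr.shape[:2]}"
        )
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must be in [0, 1]")
    if opacity == 0.0:
        return arr.astype(np.uint8, copy=True)
    cmap = colormaps[colormap]
    colored = cmap(gmap.normalized())[..., :3] * 255.0
    blended = (1.0 - opacity) * arr.astype(np.float64) + opacity * colored
    return np.clip(np.rint(blended), 0, 255).astype(np.uint8)
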