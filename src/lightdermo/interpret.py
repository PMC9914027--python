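"""GradCAM saliency maps.

For a target class score y_k (the pre-softmax logit, which makes the map
invariant to constant shifts of all logits), the gradient of y_k with respect
to a tapped convolutional feature map A is spatially averaged into one weight
per channel; the map is ReLU(sum_c w_c * A_c), bilinearly upsampled to the
input resolution and min-max normalized into [0, 1] (identically zero maps
stay zero).  The default tap is the stage-4 squeeze-and-excitation output,
the last spatial feature map before global pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._tensor import Tensor
from .model import ShuffleNetLight

__all__ = ["GradCAMMap", "gradcam", "overlay"]


@dataclass
class GradCAMMap:
    heatmap: np.ndarray  # (H, W) in [0, 1] at input resolution
    raw: np.ndarray  # the unnormalized low-resolution map
    target_class: int
    layer: str

    def mass_centroid(self) -> tuple[float, float]:
        """(row, col) centroid of heatmap mass; image centre if empty."""
        total = self.heatmap.sum()
        h, w = self.heatmap.shape
        if total <= 0:
            return (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        return (
            float((self.heatmap * yy).sum() / total),
            float((self.heatmap * xx).sum() / total),
        )


def gradcam(
    model: ShuffleNetLight,
    image: np.ndarray,
    target_class: int,
    layer: str = "stage4.se",
) -> GradCAMMap:
    """Class-discriminative saliency for one preprocessed image.

    ``image`` is (3, S, S) or (S, S, 3), float in [0, 1].  ``layer`` must be
    one of the model's tap names (the per-stage SE outputs).
    """
    if layer not in ShuffleNetLight.TAP_NAMES:
        raise ValueError(
            f"unknown tap layer {layer!r}; valid taps: {list(ShuffleNetLight.TAP_NAMES)}"
        )
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3 and image.shape[2] == 3:
        image = image.transpose(2, 0, 1)
    x = Tensor(image[None])
    was_training = model.training
    model.eval()
    taps: dict[str, Tensor] = {}
    logits = model.forward(x, taps=taps)
    model.train(was_training)
    seed = np.zeros_like(logits.data)
    seed[0, int(target_class)] = 1.0
    logits.backward(seed)
    activ = taps[layer]
    grad = activ.grad
    if grad is None:
        grad = np.zeros_like(activ.data)
    weights = grad.mean(axis=(2, 3))  # (1, C)
    raw = np.maximum((weights[:, :, None, None] * activ.data).sum(axis=1)[0], 0.0)
    size = image.shape[1], image.shape[2]
    heat = ndimage.zoom(raw, (size[0] / raw.shape[0], size[1] / raw.shape[1]), order=1)
    heat = heat[: size[0], : size[1]]
    peak = heat.max()
    if peak > 0:
        heat = heat / peak
    return GradCAMMap(
        heatmap=heat.astype(np.float32),
        raw=raw.astype(np.float32),
        target_class=int(target_class),
        layer=layer,
    )


def overlay(image: np.ndarray, cam: GradCAMMap, alpha: float = 0.4) -> np.ndarray:
    """Blend the heatmap over the image with a fixed perceptual colormap."""
    import matplotlib

    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3 and image.shape[0] == 3:
        image = image.transpose(1, 2, 0)
    colored = matplotlib.colormaps["inferno"](cam.heatmap)[..., :3].astype(np.float32)
    return np.clip((1 - alpha) * image + alpha * colored, 0.0, 1.0)
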