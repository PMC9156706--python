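"""Grad-CAM saliency for the stage classifiers.

The gradient of the target class's softmax score with respect to the
deepest spatially-extended feature maps is pooled over space into
per-channel weights; the weighted sum of the maps is rectified at zero,
bilinearly upsampled to the input frame size and normalized by its
maximum, yielding a [0, 1] heatmap aligned with the B-scan pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom

from .models import TrainedModel, _preprocess
from .synthetic_data import OCTFrame

__all__ = ["Heatmap", "gradcam"]


@dataclass(frozen=True)
class Heatmap:
    """Saliency grid aligned with the input frame."""

    values: np.ndarray          # (depth_px, width_px), in [0, 1]
    target_class: int
    source_layer: str

    def __post_init__(self):
        v = self.values
        if v.min() < 0 or v.max() > 1:
            raise ValueError("heatmap values must lie in [0, 1]")


def _target_layer_index(model: TrainedModel, x: np.ndarray) -> int:
    """Index of the deepest layer whose output keeps spatial extent > 1x1."""
    idx = -1
    out = x
    for i, layer in enumerate(model.network.layers):
        out = layer.forward(out)
        if out.ndim == 4 and out.shape[1] > 1 and out.shape[2] > 1:
            idx = i
    if idx < 0:
        raise ValueError("model has no spatially-extended feature layer")
    return idx


def gradcam(model: TrainedModel, frame: OCTFrame, target_class: int) -> Heatmap:
    """Class-activation heatmap for one frame and one target class.

    Deterministic for a fixed model and frame; an identically zero gradient
    yields an all-zero heatmap.
    """
    if model.is_regressor:
        raise ValueError("Grad-CAM is defined for the classifiers")
    if not 0 <= target_class < len(model.classes):
        raise ValueError(f"target_class {target_class} out of range")

    model.network.set_training(False)
    x = _preprocess([frame], model.train_mean)
    layers = model.network.layers
    idx = _target_layer_index(model, x)

    # forward pass, keeping the target activation
    out = x
    for i, layer in enumerate(layers):
        out = layer.forward(out)
        if i == idx:
            activation = out
    logits = out

    # The class score is the softmax output (the classifier's probability
    # head), so competing-class evidence enters with negative sign.  The
    # heatmap is max-normalized, so the positive scalar p_t in
    # dp_t/dz = p_t (delta_t - p) cancels; dropping it (and unit-norming
    # the direction, in float64) keeps the map well-defined even when the
    # softmax saturates and the raw gradient would underflow to zero.
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    d_logits = -p
    d_logits[:, target_class] += 1.0
    norm = float(np.sqrt((d_logits ** 2).sum()))
    if norm > 0:
        d_logits /= norm
    grad = d_logits.astype(np.float32)
    for layer in reversed(layers[idx + 1:]):
        grad = layer.backward(grad)

    weights = grad[0].mean(axis=(0, 1))                   # channel weights
    cam = np.maximum((activation[0] * weights).sum(axis=-1), 0.0)

    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    h, w = frame.pixels.shape
    cam = zoom(cam, (h / cam.shape[0], w / cam.shape[1]), order=1,
               grid_mode=True, mode="nearest")
    cam = np.clip(cam[:h, :w], 0.0, 1.0)
    if cam.shape != (h, w):
        cam = np.pad(cam, ((0, h - cam.shape[0]), (0, w - cam.shape[1])),
                     mode="edge")

    return Heatmap(values=cam, target_class=int(target_class),
                   source_layer=f"layer[{idx}]:{type(layers[idx]).__name__}")
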