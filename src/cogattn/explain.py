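"""Feature-map extraction and Grad-CAM class localization.

Grad-CAM weights each channel of a chosen convolutional activation by the
spatial mean of the class logit's gradient with respect to that channel,
rectifies the weighted sum, upsamples it bilinearly to the input size and
min-max normalizes it to [0, 1].  The default target layer is the model's
last convolutional stage (``model.last_conv_layer``).

An all-zero map (e.g. a fully rectified-away class) normalizes to zeros
rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import transform as sktransform

from ._tensor import Tensor, no_grad
from .training import prepare_images

__all__ = ["ActivationRecord", "extract_feature_maps", "grad_cam",
           "heat_mass_in_mask", "overlay_heatmap"]


@dataclass
class ActivationRecord:
    layer: str
    activation: np.ndarray   # (C, H, W)
    gradient: np.ndarray | None  # same shape, or None if no backward ran


class _capture:
    """Temporarily wrap a submodule's forward to keep its output tensor."""

    def __init__(self, module):
        self.module = module
        self.output = None

    def __enter__(self):
        orig = self.module.forward

        def wrapped(*a, **kw):
            out = orig(*a, **kw)
            self.output = out
            return out

        object.__setattr__(self.module, "forward", wrapped)
        return self

    def __exit__(self, *exc):
        object.__delattr__(self.module, "forward")
        return False


def _prepare_one(model, image, input_size=None) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HWC RGB image")
    if input_size is None:
        input_size = (3, *image.shape[:2])
    return prepare_images(image[None].astype(np.uint8), input_size)


def _minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < 1e-12:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _resolve_layer(model, layer):
    name = layer if layer is not None else model.last_conv_layer
    return name, model.get_module(name)


def extract_feature_maps(model, image, layer: str | None = None,
                         input_size=None) -> list[np.ndarray]:
    """Per-channel H x W activations at ``layer``, min-max normalized."""
    name, module = _resolve_layer(model, layer)
    x = _prepare_one(model, image, input_size)
    was_training = model.training
    model.eval()
    try:
        with no_grad(), _capture(module) as cap:
            model(Tensor(x))
    finally:
        model.train(was_training)
    act = cap.output.data
    if act.ndim != 4:
        raise ValueError(f"layer {name!r} has no spatial extent (shape {act.shape})")
    return [_minmax(act[0, c]) for c in range(act.shape[1])]


def grad_cam(model, image, target_class: int, layer: str | None = None,
             input_size=None, return_record: bool = False):
    """Grad-CAM heat map in [0, 1] at the input resolution."""
    if not (0 <= target_class < model.num_classes):
        raise ValueError(f"target_class must lie in [0, {model.num_classes})")
    name, module = _resolve_layer(model, layer)
    x = _prepare_one(model, image, input_size)
    was_training = model.training
    model.eval()
    try:
        with _capture(module) as cap:
            logits = model(Tensor(x, requires_grad=True))
    finally:
        model.train(was_training)
    act = cap.output
    if act.data.ndim != 4:
        raise ValueError(f"layer {name!r} has no spatial extent (shape {act.data.shape})")
    onehot = np.zeros_like(logits.data)
    onehot[0, target_class] = 1.0
    (logits * onehot).sum().backward()
    grad = act.grad[0]                       # (C, H, W)
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    h, w = x.shape[2:]
    cam = sktransform.resize(cam, (h, w), order=1, preserve_range=True,
                             anti_aliasing=False)
    cam = _minmax(cam)
    if return_record:
        return cam, ActivationRecord(name, act.data[0].copy(), grad.copy())
    return cam


def heat_mass_in_mask(cam: np.ndarray, mask: np.ndarray,
                      top_fraction: float = 0.1) -> float:
    """Fraction of the top-``top_fraction`` heat mass that falls inside a
    boolean region of interest (a localization diagnostic, not a metric)."""
    if cam.shape != mask.shape:
        raise ValueError("cam and mask shapes must match")
    k = max(1, int(round(top_fraction * cam.size)))
    thresh = np.partition(cam.ravel(), -k)[-k]
    top = cam >= thresh
    denom = cam[top].sum()
    if denom <= 0:
        return 0.0
    return float(cam[top & mask].sum() / denom)


def overlay_heatmap(image: np.ndarray, cam: np.ndarray,
                    alpha: float = 0.45) -> np.ndarray:
    """Blend a red-channel rendering of the heat map over an RGB image."""
    image = np.asarray(image)
    if cam.shape != image.shape[:2]:
        cam = sktransform.resize(cam, image.shape[:2], order=1,
                                 preserve_range=True, anti_aliasing=False)
    heat = np.zeros_like(image, dtype=np.float64)
    heat[..., 0] = cam * 255.0
    heat[..., 2] = (1.0 - cam) * 80.0
    out = (1 - alpha) * image.astype(np.float64) + alpha * heat
    return np.clip(out, 0, 255).astype(np.uint8)


def save_overlay(image, cam, path) -> None:
    Image.fromarray(overlay_heatmap(image, cam)).save(path)
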