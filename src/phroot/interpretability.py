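"""Guided Grad-CAM attribution maps for segmentation predictions.

The class score for attribution is the sum of the target class's output
logits over the pixels the model actually assigns to that class (argmax =
target), making the score — and hence the attribution — invariant to logits
at pixels of other predicted classes.  Guided Backpropagation differentiates
this score with respect to the input with negative upstream gradients
blocked at every ReLU; Grad-CAM weighs a chosen convolutional layer's
activations by their spatially averaged score gradients, rectifies, and
upsamples; Guided Grad-CAM is their elementwise product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .model import UNet2, normalize_input
from .nn.tensor import Tensor, guided_relu_mode

__all__ = [
    "AttributionMap",
    "DEFAULT_CAM_LAYER",
    "class_score",
    "guided_backprop",
    "grad_cam",
    "guided_grad_cam",
]

#: Last convolution of the final decoder stage: highest-resolution semantic
#: features; present in every preset.
DEFAULT_CAM_LAYER = "de1.conv1d"


@dataclass
class AttributionMap:
    """Fused Guided Grad-CAM map plus its two components."""

    values: np.ndarray  # (H, W) fused importance scores
    target_class: int
    guided_backprop: np.ndarray  # (H, W), signed
    grad_cam: np.ndarray  # (H, W), non-negative


def _check_class(model: UNet2, target_class: int) -> None:
    if not 0 <= target_class < model.config.n_classes:
        raise ValueError(
            f"target class {target_class} outside 0..{model.config.n_classes - 1}"
        )


def class_score(
    logits: np.ndarray, predicted_mask: np.ndarray, target_class: int
) -> float:
    """Sum of target-class logits over pixels predicted as the target class."""
    logits = np.asarray(logits)
    mask = np.asarray(predicted_mask)
    if not 0 <= target_class < logits.shape[0]:
        raise ValueError(f"invalid class id {target_class}")
    return float(logits[target_class][mask == target_class].sum())


def _forward_score(
    model: UNet2, image: np.ndarray, target_class: int, record: dict | None = None
) -> tuple[Tensor | None, Tensor]:
    """Forward pass returning (score tensor or None if empty mask, input)."""
    model.eval()
    x = Tensor(normalize_input(image)[None, None], requires_grad=True)
    logits = model(x, record=record)
    predicted = np.argmax(logits.data[0], axis=0)
    select = np.zeros_like(logits.data)
    select[0, target_class][predicted == target_class] = 1.0
    if select.sum() == 0:
        return None, x
    score = (logits * Tensor(select)).sum()
    return score, x


def guided_backprop(model: UNet2, image: np.ndarray, target_class: int) -> np.ndarray:
    """Signed input-gradient map under the guided-ReLU backward rule."""
    _check_class(model, target_class)
    score, x = _forward_score(model, image, target_class)
    if score is None:
        return np.zeros(image.shape, dtype=np.float32)
    with guided_relu_mode():
        score.backward()
    return x.grad[0, 0].astype(np.float32)


def grad_cam(
    model: UNet2,
    image: np.ndarray,
    target_class: int,
    layer: str = DEFAULT_CAM_LAYER,
) -> np.ndarray:
    """ReLU-rectified, gradient-weighted activation map, upsampled to input size."""
    _check_class(model, target_class)
    record: dict = {}
    score, _ = _forward_score(model, image, target_class, record=record)
    if layer not in record:
        raise KeyError(
            f"layer {layer!r} not found; available: {sorted(record)[:8]}..."
        )
    if score is None:
        return np.zeros(image.shape, dtype=np.float32)
    score.backward()
    act = record[layer]
    weights = act.grad[0].mean(axis=(1, 2))  # channel-wise averaged gradients
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    if cam.shape != image.shape:
        cam = resize(cam, image.shape, order=1, preserve_range=True, anti_aliasing=False)
    return cam.astype(np.float32)


def guided_grad_cam(
    model: UNet2,
    image: np.ndarray,
    target_class: int,
    layer: str = DEFAULT_CAM_LAYER,
) -> AttributionMap:
    """Elementwise fusion of Guided Backpropagation and Grad-CAM."""
    gb = guided_backprop(model, image, target_class)
    cam = grad_cam(model, image, target_class, layer=layer)
    return AttributionMap(
        values=(gb * cam).astype(np.float32),
        target_class=target_class,
        guided_backprop=gb,
        grad_cam=cam,
    )


def most_predicted_classes(
    predicted_mask: np.ndarray, top_k: int = 3, skip_background: bool = True
) -> list[int]:
    """Most frequently predicted class ids, for per-image report panels."""
    labels, counts = np.unique(np.asarray(predicted_mask), return_counts=True)
    order = np.argsort(counts)[::-1]
    out = []
    for i in order:
        cid = int(labels[i])
        if skip_background and cid == 0:
            continue
        out.append(cid)
        if len(out) == top_k:
            break
    return out
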