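"""Monte Carlo Dropout epistemic-uncertainty maps.

Dropout is activated in front of every convolution of the trained network
and T stochastic forward passes are run on the same input.  The per-pixel,
per-class standard deviation of the softmax outputs across passes (population
convention, divisor T — the Monte Carlo moment estimate) is the uncertainty;
the mean softmax across passes approximates the predictive distribution.
The scalar per-image map is the standard deviation of the probability of the
per-pixel predicted class (argmax of the mean softmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import UNet2, _softmax, normalize_input
from .nn.tensor import Tensor

__all__ = ["McDropoutConfig", "UncertaintyMap", "mc_dropout_predict"]


@dataclass
class McDropoutConfig:
    """T stochastic passes at the given dropout rate, seeded independently."""

    T: int = 10
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")


@dataclass
class UncertaintyMap:
    per_class_std: np.ndarray  # (C, H, W), values in [0, 0.5]
    scalar_map: np.ndarray  # (H, W)
    mean_probs: np.ndarray  # (C, H, W), rows sum to 1 per pixel


def mc_dropout_predict(
    model: UNet2, brightfield: np.ndarray, config: McDropoutConfig
) -> UncertaintyMap:
    """Uncertainty map from T seeded stochastic forward passes."""
    x = normalize_input(brightfield)[None, None]
    model.eval()
    model.mc.active = True
    model.mc.rate = config.dropout_rate
    model.mc.rng = np.random.default_rng(config.seed)
    try:
        passes = []
        for _ in range(config.T):
            logits = model(Tensor(x)).data[0]
            passes.append(_softmax(logits, axis=0))
    finally:
        model.mc.active = False
        model.mc.rate = 0.0
        model.mc.rng = None
    stack = np.stack(passes)  # (T, C, H, W)
    mean_probs = stack.mean(axis=0)
    per_class_std = stack.std(axis=0)  # population (divisor T)
    # identical samples have exactly zero spread; mask out the float32
    # rounding residue of the mean so the T=1 / rate-0 contract is exact
    per_class_std[stack.max(axis=0) == stack.min(axis=0)] = 0.0
    predicted = np.argmax(mean_probs, axis=0)
    scalar_map = np.take_along_axis(per_class_std, predicted[None], axis=0)[0]
    return UncertaintyMap(
        per_class_std=per_class_std.astype(np.float32),
        scalar_map=scalar_map.astype(np.float32),
        mean_probs=mean_probs.astype(np.float32),
    )


def boundary_interior_summary(
    uncertainty: UncertaintyMap, mask: np.ndarray, band_px: int = 2
) -> dict:
    """Mean scalar uncertainty inside zone-transition bands vs zone interiors.

    A pixel is a boundary pixel when a differently labeled pixel lies within
    ``band_px`` (Chebyshev distance).  Reported descriptively alongside maps.
    """
    labels = np.asarray(mask)
    boundary = np.zeros_like(labels, dtype=bool)
    for dy in range(-band_px, band_px + 1):
        for dx in range(-band_px, band_px + 1):
            if dy == 0 and dx == 0:
                continue
            shifted = np.roll(np.roll(labels, dy, axis=0), dx, axis=1)
            boundary |= shifted != labels
    interior = ~boundary
    return {
        "boundary_mean_std": float(uncertainty.scalar_map[boundary].mean())
        if boundary.any()
        else float("nan"),
        "interior_mean_std": float(uncertainty.scalar_map[interior].mean())
        if interior.any()
        else float("nan"),
    }
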