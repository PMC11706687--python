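"""U-Net² segmentation model for root developmental zones.

The architecture follows the published residual-U-block (RSU) design: an
outer U-shaped encoder–decoder whose stages are themselves small U-Nets,
with dilated variants (RSU-F) at the deepest resolutions, per-stage side
outputs and a 1×1 fusion convolution.  It is adapted to a single brightfield
input channel and five output classes (background, root, EEZ, LEZ, MZ).

Normalization layers are affine-free (no learnable scale/shift); with plain
conv weights + biases this instantiation of the published full-scale layer
plan has 44,035,385 trainable parameters (44.04 M).  A reduced "tiny" preset
with the same block topology is provided for desk-scale training and tests.

Every convolution is preceded by an optional dropout slot that is inactive
during ordinary training and prediction; Monte Carlo dropout switches these
slots on at inference time (see :mod:`phroot.uncertainty`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .image_io import CLASS_NAMES, SegmentationMask
from .nn.tensor import Tensor, concat, max_pool2x2, relu, resize_bilinear

__all__ = [
    "ArchConfig",
    "ClassProbabilityMap",
    "UNet2",
    "build_model",
    "count_trainable_parameters",
    "normalize_input",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ArchConfig:
    """Architecture settings.

    scale "full" is the published full-size configuration; "tiny" keeps the
    block topology with reduced depth and filter widths for fast training.
    ``dropout_rate`` is the probability used when Monte Carlo dropout is
    switched on; it has no effect on standard training or prediction.
    """

    in_channels: int = 1
    n_classes: int = 5
    scale: str = "full"
    dropout_rate: float = 0.5

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.scale not in _PRESETS:
            raise ValueError(
                f"unknown scale preset {self.scale!r}; choose from {sorted(_PRESETS)}"
            )


@dataclass
class ClassProbabilityMap:
    """Per-pixel class scores from one forward pass (C × H × W)."""

    probs: np.ndarray
    logits: np.ndarray


class _McState:
    """Shared switch enabling dropout in front of every convolution."""

    __slots__ = ("active", "rate", "rng")

    def __init__(self):
        self.active = False
        self.rate = 0.0
        self.rng: np.random.Generator | None = None


class ConvBlock(nn.Module):
    """conv3×3 (dilated) → affine-free batch norm → ReLU, with a dropout slot."""

    def __init__(self, cin, cout, dilation, mc: _McState, rng, name: str):
        super().__init__()
        self.name = name
        self.mc = mc
        self.conv = nn.Conv2d(cin, cout, 3, dilation=dilation, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        if self.mc.active and self.mc.rate > 0:
            x = nn.dropout(x, self.mc.rate, self.mc.rng)
        return relu(self.bn(self.conv(x)))


class RSU(nn.Module):
    """Residual U-block of depth ``levels`` (internal pooling encoder–decoder)."""

    def __init__(self, levels, cin, mid, cout, mc, rng, name):
        super().__init__()
        self.levels = levels
        self.convin = ConvBlock(cin, cout, 1, mc, rng, f"{name}.convin")
        self.enc = []
        for i in range(1, levels + 1):
            ci = cout if i == 1 else mid
            dil = 2 if i == levels else 1
            blk = ConvBlock(ci, mid, dil, mc, rng, f"{name}.conv{i}")
            setattr(self, f"conv{i}", blk)
            self.enc.append(blk)
        self.dec = []
        for i in range(levels - 1, 0, -1):
            co = cout if i == 1 else mid
            blk = ConvBlock(2 * mid, co, 1, mc, rng, f"{name}.conv{i}d")
            setattr(self, f"conv{i}d", blk)
            self.dec.append(blk)

    def forward(self, x, rec=None):
        def run(blk, t):
            out = blk(t)
            if rec is not None:
                rec[blk.name] = out
            return out

        hxin = run(self.convin, x)
        feats = []
        hx = hxin
        for i, blk in enumerate(self.enc, start=1):
            h = run(blk, hx)
            feats.append(h)
            hx = max_pool2x2(h) if i <= self.levels - 2 else h
        hx = feats[-1]
        for j, blk in enumerate(self.dec):
            i = self.levels - 1 - j  # encoder level being merged
            skip = feats[i - 1]
            if hx.shape[2:] != skip.shape[2:]:
                hx = resize_bilinear(hx, skip.shape[2:])
            hx = run(blk, concat([hx, skip]))
        return hx + hxin


class RSUF(nn.Module):
    """Dilation-based residual U-block (no pooling; rates 1, 2, 4, 8)."""

    def __init__(self, cin, mid, cout, mc, rng, name):
        super().__init__()
        self.convin = ConvBlock(cin, cout, 1, mc, rng, f"{name}.convin")
        self.conv1 = ConvBlock(cout, mid, 1, mc, rng, f"{name}.conv1")
        self.conv2 = ConvBlock(mid, mid, 2, mc, rng, f"{name}.conv2")
        self.conv3 = ConvBlock(mid, mid, 4, mc, rng, f"{name}.conv3")
        self.conv4 = ConvBlock(mid, mid, 8, mc, rng, f"{name}.conv4")
        self.conv3d = ConvBlock(2 * mid, mid, 4, mc, rng, f"{name}.conv3d")
        self.conv2d = ConvBlock(2 * mid, mid, 2, mc, rng, f"{name}.conv2d")
        self.conv1d = ConvBlock(2 * mid, cout, 1, mc, rng, f"{name}.conv1d")

    def forward(self, x, rec=None):
        def run(blk, t):
            out = blk(t)
            if rec is not None:
                rec[blk.name] = out
            return out

        hxin = run(self.convin, x)
        h1 = run(self.conv1, hxin)
        h2 = run(self.conv2, h1)
        h3 = run(self.conv3, h2)
        h4 = run(self.conv4, h3)
        h3d = run(self.conv3d, concat([h4, h3]))
        h2d = run(self.conv2d, concat([h3d, h2]))
        h1d = run(self.conv1d, concat([h2d, h1]))
        return h1d + hxin


# Stage plans: (kind, levels, mid, out). kind "f" = dilated block.
_PRESETS = {
    "full": {
        "encoders": [
            ("u", 7, 32, 64),
            ("u", 6, 32, 128),
            ("u", 5, 64, 256),
            ("u", 4, 128, 512),
            ("f", 0, 256, 512),
            ("f", 0, 256, 512),
        ],
        "decoders": [  # de5 .. de1
            ("f", 0, 256, 512),
            ("u", 4, 128, 256),
            ("u", 5, 64, 128),
            ("u", 6, 32, 64),
            ("u", 7, 16, 64),
        ],
    },
    "tiny": {
        "encoders": [
            ("u", 4, 4, 8),
            ("u", 4, 4, 16),
            ("f", 0, 8, 16),
        ],
        "decoders": [  # de2, de1
            ("u", 4, 4, 8),
            ("u", 4, 4, 8),
        ],
    },
}


class UNet2(nn.Module):
    """Nested encoder–decoder of residual U-blocks with side outputs."""

    def __init__(self, config: ArchConfig, init_seed: int = 0):
        super().__init__()
        self.config = config
        self.init_seed = init_seed
        self.mc = _McState()
        rng = np.random.default_rng(init_seed)
        plan = _PRESETS[config.scale]
        n_enc = len(plan["encoders"])

        def make(kind, levels, cin, mid, cout, name):
            if kind == "f":
                return RSUF(cin, mid, cout, self.mc, rng, name)
            return RSU(levels, cin, mid, cout, self.mc, rng, name)

        cin = config.in_channels
        self.encoder_names = []
        enc_out = []
        for i, (kind, levels, mid, cout) in enumerate(plan["encoders"], start=1):
            name = f"en{i}"
            setattr(self, name, make(kind, levels, cin, mid, cout, name))
            self.encoder_names.append(name)
            enc_out.append(cout)
            cin = cout
        self.decoder_names = []
        dec_out = []
        for j, (kind, levels, mid, cout) in enumerate(plan["decoders"]):
            i = n_enc - 1 - j  # decoder index de_i, i = n_enc-1 .. 1
            prev = enc_out[-1] if j == 0 else dec_out[-1]
            name = f"de{i}"
            setattr(self, name, make(kind, levels, prev + enc_out[i - 1], mid, cout, name))
            self.decoder_names.append(name)
            dec_out.append(cout)
        # side outputs: de1 .. de(n-1), then the deepest encoder stage
        side_channels = list(reversed(dec_out)) + [enc_out[-1]]
        self.n_sides = len(side_channels)
        for k, ch in enumerate(side_channels, start=1):
            setattr(self, f"side{k}", nn.Conv2d(ch, config.n_classes, 3, rng=rng))
        self.fuse = nn.Conv2d(
            self.n_sides * config.n_classes, config.n_classes, 1, rng=rng
        )

    def _side(self, k: int, feat: Tensor, out_hw) -> Tensor:
        conv: nn.Conv2d = getattr(self, f"side{k}")
        if self.mc.active and self.mc.rate > 0:
            feat = nn.dropout(feat, self.mc.rate, self.mc.rng)
        s = conv(feat)
        return resize_bilinear(s, out_hw)

    def forward(self, x: Tensor, record: dict | None = None) -> Tensor:
        """Return fused logits (N × C × H × W).

        ``record``, if given, collects every conv-block activation by name
        (e.g. ``"de1.conv1d"``) for gradient-based attribution.
        """
        out_hw = x.shape[2:]
        feats = []
        hx = x
        n_enc = len(self.encoder_names)
        for i, name in enumerate(self.encoder_names, start=1):
            hx = getattr(self, name)(hx, rec=record)
            feats.append(hx)
            if i < n_enc:
                hx = max_pool2x2(hx)
        dec_feats = []
        for j, name in enumerate(self.decoder_names):
            i = n_enc - 1 - j
            skip = feats[i - 1]
            if hx.shape[2:] != skip.shape[2:]:
                hx = resize_bilinear(hx, skip.shape[2:])
            hx = getattr(self, name)(concat([hx, skip]), rec=record)
            dec_feats.append(hx)
        sides = [self._side(k + 1, f, out_hw) for k, f in enumerate(reversed(dec_feats))]
        sides.append(self._side(self.n_sides, feats[-1], out_hw))
        fused_in = concat(sides)
        if self.mc.active and self.mc.rate > 0:
            fused_in = nn.dropout(fused_in, self.mc.rate, self.mc.rng)
        fused = self.fuse(fused_in)
        if record is not None:
            record["fuse"] = fused
        return fused


def build_model(config: ArchConfig, init_seed: int = 0) -> UNet2:
    """Instantiate U-Net² with seed-controlled weight initialization."""
    return UNet2(config, init_seed=init_seed)


def count_trainable_parameters(model: nn.Module) -> int:
    """Exact number of trainable weight and bias elements."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


def parameter_table(model: nn.Module) -> list[tuple[str, tuple, int]]:
    """Per-parameter (name, shape, count) listing, in registration order."""
    return [(n, p.data.shape, int(p.data.size)) for n, p in model.named_parameters()]


def normalize_input(image: np.ndarray) -> np.ndarray:
    """Per-image min–max normalization to [0, 1] (the training convention)."""
    img = np.asarray(image, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img


def _softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def predict(
    model: UNet2, brightfield: np.ndarray
) -> tuple[ClassProbabilityMap, SegmentationMask]:
    """Segment a single brightfield image (H × W).

    The image is min–max normalized, passed through the network with dropout
    inactive, and the per-pixel argmax taken over class probabilities (ties
    broken toward the lowest class index, i.e. background).
    """
    model.eval()
    x = normalize_input(brightfield)[None, None]
    logits = model(Tensor(x)).data[0]
    probs = _softmax(logits, axis=0)
    labels = np.argmax(probs, axis=0).astype(np.uint8)
    return ClassProbabilityMap(probs=probs, logits=logits), SegmentationMask(labels)


def save_checkpoint(
    model: UNet2, path: str | Path, extra: dict | None = None
) -> Path:
    """Write weights (.npz) plus a JSON sidecar with the architecture config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "arch": dataclasses.asdict(model.config),
        "init_seed": model.init_seed,
        "class_names": CLASS_NAMES,
    }
    sidecar.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[UNet2, dict]:
    """Rebuild a model from a checkpoint and its JSON sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing checkpoint sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    config = ArchConfig(**sidecar["arch"])
    model = build_model(config, init_seed=int(sidecar.get("init_seed", 0)))
    with np.load(path) as npz:
        model.load_state_dict(dict(npz))
    return model, sidecar
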