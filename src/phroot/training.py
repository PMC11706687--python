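"""Dataset splitting, augmentation, focal loss, IoU and deterministic training.

Training optimizes a focal loss over the fused network output with Adam.
All randomness (shuffling, augmentation draws) derives from the config seed
through named substreams; since the compute core is pure numpy, two runs
with the same seed produce bit-identical weights and metrics.  An unseeded
run draws its entropy from the operating system instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import AffineTransform, warp

from .image_io import CLASS_NAMES, SegmentationMask
from .model import UNet2, normalize_input, predict
from .nn import Adam
from .nn.tensor import Tensor, log_softmax

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "IoUReport",
    "TrainingDiverged",
    "split_dataset",
    "augment_pair",
    "focal_loss",
    "iou",
    "evaluate",
    "train",
]

SPECIALIZED_CLASSES = ("EEZ", "LEZ", "MZ")


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class AugmentConfig:
    """Geometric augmentation limits, matched to the acquisition setup."""

    max_rotation_deg: float = 10.0
    max_shift_px: float = 26.0
    max_scale_px: float = 51.0
    per_op_probability: float = 0.5

    def __post_init__(self):
        if min(self.max_rotation_deg, self.max_shift_px, self.max_scale_px) < 0:
            raise ValueError("augmentation limits must be non-negative")
        if not 0 <= self.per_op_probability <= 1:
            raise ValueError("per_op_probability must be in [0, 1]")


@dataclass
class TrainConfig:
    split_fractions: tuple = (0.8, 0.1, 0.1)
    epochs: int = 74
    batch_size: int = 4
    learning_rate: float = 1e-3
    focal_gamma: float = 2.0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int | None = 0
    deterministic: bool = True

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class IoUReport:
    """Per-class mean IoU over evaluated images.

    ``mean_iou`` averages the specialized classes (EEZ, LEZ, MZ) used for
    model selection; ``mean_iou_all`` averages every evaluable class.
    Classes with an empty union in every image are reported as NaN and
    excluded from the means.
    """

    per_class_iou: dict
    mean_iou: float
    mean_iou_all: float
    n_images: int


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(
    sample_ids: Sequence[str],
    fractions: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list, list, list]:
    """Seeded train/val/test partition.

    Ids are sorted lexicographically, shuffled with the seed, and cut into
    floor(n·f) blocks; remainder ids go to the training set.
    """
    ids = sorted(str(s) for s in sample_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    n = len(ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    n_val = math.floor(n * fractions[1])
    n_test = math.floor(n * fractions[2])
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) == 0:
        raise ValueError(f"split of {n} ids leaves an empty subset")
    train_ids = shuffled[:n_train]
    val_ids = shuffled[n_train : n_train + n_val]
    test_ids = shuffled[n_train + n_val :]
    return train_ids, val_ids, test_ids


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply rotation / shift / scale, each with its own probability.

    One combined affine transform (rotate, then shift, then scale about the
    image center) warps the image bilinearly and the mask nearest-neighbour,
    so both stay on the same pixel grid and mask labels are preserved.
    """
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    center = AffineTransform(translation=(-cx, -cy))
    uncenter = AffineTransform(translation=(cx, cy))
    tform = AffineTransform()
    if rng.random() < config.per_op_probability:
        angle = np.deg2rad(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
        tform = center + AffineTransform(rotation=angle) + uncenter
    if rng.random() < config.per_op_probability:
        dx = rng.uniform(-config.max_shift_px, config.max_shift_px)
        dy = rng.uniform(-config.max_shift_px, config.max_shift_px)
        tform = tform + AffineTransform(translation=(dx, dy))
    if rng.random() < config.per_op_probability:
        delta = rng.uniform(-config.max_scale_px, config.max_scale_px)
        factor = max(w + delta, 8.0) / w
        tform = tform + (center + AffineTransform(scale=factor) + uncenter)
    params = tform.params
    if np.allclose(params, np.eye(3)):
        return image.copy(), mask.copy()
    inv = np.linalg.inv(params)
    out_img = warp(
        image.astype(np.float32), inv, order=1, preserve_range=True, mode="constant"
    ).astype(np.float32)
    out_mask = warp(
        mask, inv, order=0, preserve_range=True, mode="constant", cval=0
    ).astype(mask.dtype)
    return out_img, out_mask


# ---------------------------------------------------------------------------
# losses and metrics
# ---------------------------------------------------------------------------

def focal_loss(
    probs: np.ndarray, target: np.ndarray, gamma: float = 2.0, eps: float = 1e-8
) -> float:
    """Mean over pixels of −(1−p_t)^γ · log p_t (p_t floored at ``eps``).

    ``probs`` is (C, H, W) softmax output; ``target`` the integer mask.
    With γ = 0 this is the mean cross-entropy.
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    if probs.shape[1:] != target.shape:
        raise ValueError("probs and target shapes do not match")
    pt = np.take_along_axis(probs, target[None].astype(int), axis=0)[0]
    pt = np.maximum(pt, eps)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def focal_loss_logits(
    logits: Tensor, target: np.ndarray, gamma: float, eps: float = 1e-8
) -> Tensor:
    """Differentiable focal loss from (N, C, H, W) logits."""
    n, c = logits.shape[:2]
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    np.put_along_axis(onehot, target[:, None].astype(int), 1.0, axis=1)
    logp = log_softmax(logits, axis=1)
    pt_log = (logp * Tensor(onehot)).sum(axis=1).clip_min(float(np.log(eps)))
    pt = pt_log.exp()
    return ((1.0 - pt).pow(gamma) * (-pt_log)).mean()


def iou(pred, truth, class_id: int) -> float:
    """Per-class Jaccard index |pred ∧ truth| / |pred ∨ truth|.

    Returns NaN when the union is empty (class absent from both masks).
    """
    p = pred.labels if isinstance(pred, SegmentationMask) else np.asarray(pred)
    t = truth.labels if isinstance(truth, SegmentationMask) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("pred and truth shapes differ")
    pc = p == class_id
    tc = t == class_id
    union = np.logical_or(pc, tc).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(pc, tc).sum() / union)


def evaluate(model: UNet2, dataset: Sequence[tuple]) -> IoUReport:
    """Mean per-class IoU over a labeled dataset of (brightfield, mask) pairs.

    Images where a class has an empty union are excluded from that class's
    mean; ``mean_iou`` averages EEZ/LEZ/MZ.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    per_class: dict[str, list[float]] = {name: [] for name in CLASS_NAMES}
    for image, mask in dataset:
        truth = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
        _, pred = predict(model, image)
        for cid, name in enumerate(CLASS_NAMES):
            value = iou(pred.labels, truth, cid)
            if not np.isnan(value):
                per_class[name].append(value)
    means = {
        name: (float(np.mean(v)) if v else float("nan"))
        for name, v in per_class.items()
    }
    specialized = [means[c] for c in SPECIALIZED_CLASSES if not np.isnan(means[c])]
    all_defined = [v for v in means.values() if not np.isnan(v)]
    return IoUReport(
        per_class_iou=means,
        mean_iou=float(np.mean(specialized)) if specialized else float("nan"),
        mean_iou_all=float(np.mean(all_defined)) if all_defined else float("nan"),
        n_images=len(dataset),
    )


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _prepare(dataset: Sequence[tuple]) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for image, mask in dataset:
        m = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
        pairs.append((np.asarray(image, dtype=np.float32), m.astype(np.uint8)))
    return pairs


def train(
    model: UNet2,
    train_data: Sequence[tuple],
    val_data: Sequence[tuple],
    config: TrainConfig,
) -> tuple[UNet2, list[dict]]:
    """Optimize the model; returns (model-with-best-weights, per-epoch metrics).

    The checkpointed state is the epoch with the highest validation mean IoU
    over EEZ/LEZ/MZ (earliest epoch wins ties).  Raises
    :class:`TrainingDiverged` on a non-finite loss.
    """
    if config.epochs < 1:
        raise ValueError("epochs must be >= 1")
    if not train_data:
        raise ValueError("empty training set")
    train_pairs = _prepare(train_data)
    val_pairs = _prepare(val_data)
    entropy = (
        np.random.SeedSequence(config.seed)
        if config.deterministic and config.seed is not None
        else np.random.SeedSequence()
    )
    shuffle_rng, augment_rng = (np.random.default_rng(s) for s in entropy.spawn(2))
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    metrics: list[dict] = []
    best_state: dict | None = None
    best_iou = -np.inf
    for epoch in range(config.epochs):
        model.train()
        order = shuffle_rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            images, targets = [], []
            for i in batch_idx:
                img, msk = train_pairs[i]
                if config.augment.per_op_probability > 0:
                    img, msk = augment_pair(img, msk, config.augment, augment_rng)
                images.append(normalize_input(img))
                targets.append(msk)
            x = Tensor(np.stack(images)[:, None])
            target = np.stack(targets)
            logits = model(x)
            loss = focal_loss_logits(logits, target, config.focal_gamma)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: {loss.item()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        report = evaluate(model, val_pairs) if val_pairs else None
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if report is not None:
            row.update(
                {f"iou_{name}": value for name, value in report.per_class_iou.items()}
            )
            row["mean_iou"] = report.mean_iou
            if report.mean_iou > best_iou:
                best_iou = report.mean_iou
                best_state = {k: v.copy() for k, v in model.state_dict().items()}
        metrics.append(row)
    if best_state is not None:
        model.load_state_dict(best_state)
    return model, metrics
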