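"""Synthetic root-tip image generator.

Renders labeled 4-channel images with the structure the analysis assumes:
a curved root band whose developmental zones (meristematic, early- and
late-elongation) are tiled with "cells" obeying the morphological
length/width rules — MZ < 1, EEZ in [1, 2], LEZ > 2 — drawn as dark borders
on a bright interior in both brightfield channels.  The 405 nm fluorescence
channel is a flat base intensity inside the root; the 458 nm channel is the
base scaled by the zone's true 458/405 ratio (times multiplicative noise),
so that with zero noise the ground-truth zone-mean ratio equals the
configured value exactly.  A multiplicative treatment effect on the ratio is
applied only to the wildtype line under the effect treatment, emulating a
hormone response that a receptor mutant lacks.

Generation is bit-exact reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import (
    CHANNEL_ROLES,
    MultiChannelImage,
    SampleRecord,
    SegmentationMask,
    write_image,
    write_metadata_table,
)

__all__ = ["SyntheticConfig", "SyntheticSample", "generate_sample", "generate_dataset"]

ZONE_LABELS = {"background": 0, "root": 1, "EEZ": 2, "LEZ": 3, "MZ": 4}

# Base fluorescence intensity inside the root (405 nm channel).  Chosen so
# that products with ratios in steps of 0.05 are integral, keeping 16-bit
# storage exact for the default ratio values.
BASE_FL405 = 20000.0
BACKGROUND_FL405 = 300.0
BACKGROUND_FL458 = 150.0
CELL_INTERIOR = 52000
CELL_BORDER = 12000
BACKGROUND_BF = 30000


def _default_cell_geometry() -> dict:
    # (length range, width range) in pixels; length is along the root axis.
    return {
        "MZ": ((3.0, 5.0), (6.0, 9.0)),       # L/W < 1
        "EEZ": ((8.0, 12.0), (6.0, 8.0)),     # L/W in [1, 2]
        "LEZ": ((17.0, 24.0), (6.0, 8.0)),    # L/W > 2
        "root": ((10.0, 14.0), (7.0, 9.0)),
    }


def _default_zone_ratio() -> dict:
    return {"root": 1.8, "MZ": 1.5, "EEZ": 2.0, "LEZ": 2.5}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    ``zone_layout`` lists (zone, span-in-pixels) from the root tip upward;
    the remainder of the root band above the last span is generic root
    tissue.  ``treatment_effect`` multiplies every zone ratio when
    ``line == wildtype_line`` and ``treatment == effect_treatment``.
    """

    image_size: int = 512
    root_width: int | None = None
    zone_layout: tuple = ()  # filled from image_size when empty
    cell_geometry: dict = field(default_factory=_default_cell_geometry)
    true_zone_ratio: dict = field(default_factory=_default_zone_ratio)
    treatment_effect: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0
    curvature: float = 0.08
    wildtype_line: str = "Col-0"
    effect_treatment: str = "BL"

    def __post_init__(self):
        if self.root_width is None:
            self.root_width = max(12, int(round(self.image_size * 0.38)))
        if not self.zone_layout:
            s = self.image_size
            self.zone_layout = (
                ("root", max(3, int(0.05 * s))),
                ("MZ", int(0.24 * s)),
                ("EEZ", int(0.24 * s)),
                ("LEZ", int(0.28 * s)),
            )
        for zone, (lrange, wrange) in self.cell_geometry.items():
            lo = lrange[0] / wrange[1]
            hi = lrange[1] / wrange[0]
            if zone == "MZ" and hi >= 1:
                raise ValueError("MZ cell length/width must stay below 1")
            if zone == "EEZ" and (lo < 1 or hi > 2):
                raise ValueError("EEZ cell length/width must stay within [1, 2]")
            if zone == "LEZ" and lo <= 2:
                raise ValueError("LEZ cell length/width must exceed 2")
        for zone, ratio in self.true_zone_ratio.items():
            if ratio <= 0:
                raise ValueError(f"true_zone_ratio[{zone!r}] must be positive")
        if not 0 <= self.treatment_effect:
            raise ValueError("treatment_effect must be non-negative")


@dataclass
class SyntheticSample:
    image: MultiChannelImage
    mask: SegmentationMask
    truth: dict  # zone -> effective true ratio in this sample
    line: str
    treatment: str


def effective_zone_ratios(config: SyntheticConfig, line: str, treatment: str) -> dict:
    """True per-zone ratios after applying the treatment effect if due."""
    ratios = dict(config.true_zone_ratio)
    if line == config.wildtype_line and treatment == config.effect_treatment:
        ratios = {z: r * config.treatment_effect for z, r in ratios.items()}
    return ratios


def generate_sample(
    config: SyntheticConfig, line: str, treatment: str
) -> SyntheticSample:
    """Render one labeled 4-channel sample; bit-identical for a fixed config."""
    size = config.image_size
    rng = np.random.default_rng(config.seed)

    # Curved centerline x(y): gentle quadratic; tip near the bottom.
    tip_y = int(round(size * 0.88))
    c0 = size / 2 + rng.uniform(-0.05, 0.05) * size
    c1 = rng.uniform(-0.15, 0.15)
    c2 = rng.uniform(-1.0, 1.0) * config.curvature / size
    ys = np.arange(size, dtype=np.float64)
    centerline = c0 + c1 * (ys - tip_y) + c2 * (ys - tip_y) ** 2

    yy, xx = np.meshgrid(ys, np.arange(size, dtype=np.float64), indexing="ij")
    lateral = xx - centerline[:, None]  # signed distance from centerline
    axial = tip_y - yy  # distance above the tip along the axis
    in_band = (np.abs(lateral) <= config.root_width / 2) & (axial >= 0)

    # Zone assignment along the axis.
    spans = list(config.zone_layout)
    total_span = sum(s for _, s in spans)
    if total_span > tip_y:
        raise ValueError(
            f"zone spans ({total_span} px) exceed the root length ({tip_y} px)"
        )
    labels = np.zeros((size, size), dtype=np.uint8)
    zone_of_axial = np.full(size + 1, ZONE_LABELS["root"], dtype=np.uint8)
    zone_name_at = {}
    start = 0
    for zone, span in spans:
        zone_of_axial[start : start + span] = ZONE_LABELS[zone]
        zone_name_at[zone] = (start, start + span)
        start += span
    ax_idx = np.clip(axial.astype(int), 0, size)
    labels[in_band] = zone_of_axial[ax_idx[in_band]]

    requested = {z for z, _ in spans} | {"root"}
    present = {name for name, lab in ZONE_LABELS.items() if np.any(labels == lab)}
    missing = requested - present
    if missing:
        raise ValueError(f"configured zones not rendered: {sorted(missing)}")

    # Brightfield: bright cell interiors with dark borders, per-zone grids.
    bf = np.full((size, size), float(BACKGROUND_BF))
    interior = CELL_INTERIOR * (1.0 + 0.02 * np.sin(yy / 7.0) * np.sin(xx / 11.0))
    bf[in_band] = interior[in_band]
    border = np.zeros((size, size), dtype=bool)
    u = lateral + config.root_width / 2  # 0 .. root_width across the band
    geometry = dict(config.cell_geometry)
    geometry.setdefault("root", ((10.0, 14.0), (7.0, 9.0)))
    for zone, (lrange, wrange) in geometry.items():
        lab = ZONE_LABELS[zone]
        cell_len = rng.uniform(*lrange)
        cell_wid = rng.uniform(*wrange)
        phase_a = rng.uniform(0, cell_len)
        phase_u = rng.uniform(0, cell_wid)
        zone_px = labels == lab
        line_a = np.mod(axial + phase_a, cell_len) < 1.2
        line_u = np.mod(u + phase_u, cell_wid) < 1.2
        border |= zone_px & (line_a | line_u)
    # root band outline
    edge = in_band & (np.abs(np.abs(lateral) - config.root_width / 2) < 1.0)
    border |= edge
    bf[border] = CELL_BORDER
    bf405 = np.clip(np.round(bf), 0, 65535).astype(np.uint16)
    bf458 = bf405.copy()

    # Fluorescence channels.
    ratios = effective_zone_ratios(config, line, treatment)
    fl405 = np.full((size, size), BACKGROUND_FL405)
    fl405[in_band] = BASE_FL405
    ratio_map = np.full((size, size), BACKGROUND_FL458 / BACKGROUND_FL405)
    for zone, r in ratios.items():
        ratio_map[labels == ZONE_LABELS[zone]] = r
    fl458 = fl405 * ratio_map
    if config.noise_sd > 0:
        factor = 1.0 + config.noise_sd * rng.standard_normal((size, size))
        fl458 = fl458 * np.clip(factor, 0.05, None)
    fl405 = np.clip(np.round(fl405), 0, 65535).astype(np.uint16)
    fl458 = np.clip(np.round(fl458), 0, 65535).astype(np.uint16)

    pixels = np.stack([fl405, bf405, fl458, bf458], axis=0)
    image = MultiChannelImage(pixels=pixels, channel_roles=CHANNEL_ROLES)
    return SyntheticSample(
        image=image,
        mask=SegmentationMask(labels),
        truth=ratios,
        line=line,
        treatment=treatment,
    )


def generate_dataset(
    config: SyntheticConfig,
    n_per_group: int,
    groups: list[tuple[str, str]],
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate ``n_per_group`` samples per (line, treatment) group.

    Per-sample seeds are derived as ``config.seed + sample_index`` so samples
    are distinct yet the whole dataset is reproducible.  When ``out_dir`` is
    given, each sample is written as an OME-TIFF (mask as a 5th channel) and
    a tab-separated metadata table ``samples.tsv`` is created.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not groups:
        raise ValueError("groups must not be empty")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    samples: list[SyntheticSample] = []
    records: list[SampleRecord] = []
    rows = []
    index = 0
    for line, treatment in groups:
        for k in range(n_per_group):
            cfg = replace(config, seed=config.seed + index)
            sample = generate_sample(cfg, line, treatment)
            sample_id = f"{line}_{treatment}_{k:03d}".replace(" ", "-")
            file_name = f"{sample_id}.ome.tif"
            if out_path is not None:
                write_image(sample.image, out_path / file_name, mask=sample.mask)
            samples.append(sample)
            records.append(
                SampleRecord(
                    sample_id=sample_id, line=line, treatment=treatment, file=file_name
                )
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "line": line,
                    "treatment": treatment,
                    "file": file_name,
                }
            )
            index += 1
    metadata = pd.DataFrame(rows)
    if out_path is not None:
        write_metadata_table(records, out_path / "samples.tsv")
    return samples, metadata
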