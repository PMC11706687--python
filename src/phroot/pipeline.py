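"""End-to-end orchestration: simulate, train, analyze, report.

``run_pipeline`` ingests a metadata table plus images, segments each sample
with a trained U-Net², computes the 458/405 ratio image, Monte Carlo Dropout
uncertainty and Guided Grad-CAM attribution maps, appends every derived
layer to the sample's OME-TIFF, aggregates per-zone mean ratios and Welch
group comparisons into CSV tables, renders an HTML report and writes a run
manifest.  All randomness flows from one top-level seed through named
substreams; a fixed seed yields byte-identical CSV outputs across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .image_io import (
    CLASS_NAMES,
    MultiChannelImage,
    SampleRecord,
    read_image,
    read_mask,
    read_metadata_table,
    write_result_image,
)
from .interpretability import guided_grad_cam, most_predicted_classes
from .model import ArchConfig, UNet2, load_checkpoint, predict, save_checkpoint
from .ratiometrics import (
    ZONES_OF_INTEREST,
    comparisons_frame,
    compute_ratio_image,
    group_statistics,
    measures_frame,
    zone_mean_ratio,
)
from .report import render_report, sample_panel_figure, _fig_to_data_uri
from .synthetic import SyntheticConfig, generate_dataset
from .training import TrainConfig, evaluate, split_dataset, train
from .uncertainty import McDropoutConfig, mc_dropout_predict

logger = logging.getLogger("phroot")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "train_command",
    "simulate_command",
]


@dataclass
class PipelineConfig:
    input_table: str
    model_checkpoint: str
    output_dir: str
    mc_dropout: McDropoutConfig = field(default_factory=McDropoutConfig)
    attribution: bool = True
    attribution_top_k: int = 3
    comparisons: list | None = None
    reference_line: str = "Col-0"
    control_treatment: str = "mock"
    seed: int = 0
    zones: tuple = ZONES_OF_INTEREST
    render_html: bool = True


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    per_sample: dict
    timings: dict
    seeds: dict

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _analyze_sample(
    model: UNet2,
    image: MultiChannelImage,
    config: PipelineConfig,
    mc_seed: int,
    sample_id: str,
):
    bf = image.channel("bf405").astype(np.float32)
    prob_map, mask = predict(model, bf)
    ratio = compute_ratio_image(image)
    mc_cfg = dataclasses.replace(config.mc_dropout, seed=mc_seed)
    unc = mc_dropout_predict(model, bf, mc_cfg)
    attributions: dict[int, np.ndarray] = {}
    if config.attribution:
        for cid in most_predicted_classes(mask.labels, top_k=config.attribution_top_k):
            attributions[cid] = guided_grad_cam(model, bf, cid).values
    measures = [
        zone_mean_ratio(ratio, mask, zone, sample_id=sample_id)
        for zone in config.zones
    ]
    return prob_map, mask, ratio, unc, attributions, measures


def run_pipeline(config: PipelineConfig):
    """Run the full analysis; returns (measures, comparisons, manifest).

    Per-sample failures are logged and skipped; the run only fails if every
    sample fails (or the checkpoint is incompatible, which fails fast).
    """
    t_start = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, sidecar = load_checkpoint(config.model_checkpoint)
    records = read_metadata_table(config.input_table, check_files=False)
    seed_seq = np.random.SeedSequence(config.seed)
    mc_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(len(records))]
    per_sample: dict[str, str] = {}
    all_measures = []
    ok_records: list[SampleRecord] = []
    panels = []
    timings: dict[str, float] = {}
    for record, mc_seed in zip(records, mc_seeds):
        t0 = time.time()
        try:
            image = read_image(record.file)
            _, mask, ratio, unc, attributions, measures = _analyze_sample(
                model, image, config, mc_seed, record.sample_id
            )
            layers = {
                "segmentation": mask.labels.astype(np.float32),
                "ratio": ratio.X,
                "uncertainty": unc.scalar_map,
            }
            for cid in range(model.config.n_classes):
                layers[f"uncertainty_{CLASS_NAMES[cid]}"] = unc.per_class_std[cid]
            for cid, attr in attributions.items():
                layers[f"attribution_{CLASS_NAMES[cid]}"] = attr
            write_result_image(
                image, out_dir / f"{record.sample_id}.result.ome.tif", layers
            )
            if config.render_html:
                fig = sample_panel_figure(
                    image.channel("bf405"),
                    mask.labels,
                    np.where(ratio.valid, ratio.X, np.nan),
                    unc.scalar_map,
                    attributions,
                )
                panels.append((record.sample_id, _fig_to_data_uri(fig)))
            all_measures.extend(measures)
            ok_records.append(record)
            per_sample[record.sample_id] = "ok"
            absent = [m.zone for m in measures if m.missing]
            if absent:
                logger.warning(
                    "sample %s: zones absent from prediction: %s",
                    record.sample_id,
                    absent,
                )
        except Exception as exc:  # per-sample isolation
            logger.error("sample %s failed: %s", record.sample_id, exc)
            per_sample[record.sample_id] = f"failed: {exc}"
        timings[record.sample_id] = round(time.time() - t0, 3)
    if not ok_records:
        raise RuntimeError("all samples failed")
    measures = measures_frame(all_measures, ok_records)
    comparisons = comparisons_frame(
        group_statistics(
            all_measures,
            ok_records,
            comparisons=config.comparisons,
            reference_line=config.reference_line,
            control_treatment=config.control_treatment,
        )
    )
    measures.to_csv(out_dir / "measures.csv", index=False, float_format="%.10g")
    comparisons.to_csv(out_dir / "comparisons.csv", index=False, float_format="%.10g")
    manifest = RunManifest(
        version=__version__,
        config_hash=_config_hash(config),
        seed=config.seed,
        per_sample=per_sample,
        timings={"total_s": round(time.time() - t_start, 3), **timings},
        seeds={r.sample_id: s for r, s in zip(records, mc_seeds)},
    )
    manifest.write(out_dir / "manifest.json")
    if config.render_html:
        note = (
            f"phroot {__version__} · model scale {sidecar['arch']['scale']} · "
            f"seed {config.seed} · config {manifest.config_hash}"
        )
        render_report(out_dir / "report.html", measures, comparisons, panels,
                      manifest_note=note)
    return measures, comparisons, manifest


def train_command(
    dataset_dir: str | Path,
    out_dir: str | Path,
    train_config: TrainConfig | None = None,
    arch_config: ArchConfig | None = None,
    init_seed: int = 0,
):
    """Train a segmentation model from a simulated/curated dataset directory.

    Expects ``samples.tsv`` plus per-sample OME-TIFFs with a mask channel.
    Writes ``model.npz`` + JSON sidecar and ``metrics.csv`` (one row per
    epoch).  Returns (model, metrics, test IoU report).
    """
    from .model import build_model  # local to keep import graph simple

    dataset_dir = Path(dataset_dir)
    if not dataset_dir.exists():
        raise FileNotFoundError(dataset_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_config = train_config or TrainConfig()
    arch_config = arch_config or ArchConfig(scale="tiny")
    records = read_metadata_table(dataset_dir / "samples.tsv")
    data = {}
    for record in records:
        image = read_image(record.file)
        mask = read_mask(record.file)
        if mask is None:
            raise ValueError(f"{record.file}: no mask channel for training")
        data[record.sample_id] = (image.channel("bf405").astype(np.float32), mask.labels)
    train_ids, val_ids, test_ids = split_dataset(
        list(data), train_config.split_fractions, seed=train_config.seed or 0
    )
    model = build_model(arch_config, init_seed=init_seed)
    model, metrics = train(
        model, [data[i] for i in train_ids], [data[i] for i in val_ids], train_config
    )
    report = evaluate(model, [data[i] for i in test_ids])
    pd.DataFrame(metrics).to_csv(out_dir / "metrics.csv", index=False)
    save_checkpoint(
        model,
        out_dir / "model.npz",
        extra={
            "train_config": dataclasses.asdict(train_config),
            "split": {"train": train_ids, "val": val_ids, "test": test_ids},
            "test_iou": report.per_class_iou,
            "test_mean_iou": report.mean_iou,
        },
    )
    return model, metrics, report


def simulate_command(
    config: SyntheticConfig,
    groups: list[tuple[str, str]],
    n_per_group: int,
    out_dir: str | Path,
):
    """Write a synthetic dataset (OME-TIFFs + samples.tsv) to ``out_dir``."""
    return generate_dataset(config, n_per_group, groups, out_dir=out_dir)
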