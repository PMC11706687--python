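"""Pixel-wise 458/405 ratio images, zone means and Welch group statistics.

The ratiometric HPTS readout: the deprotonated dye form is excited at
458 nm, the protonated form at 405 nm, so the per-pixel 458/405 intensity
ratio tracks apoplastic pH.  The per-zone summary is the masked mean
Σ(X⊙Y)/ΣY with X the ratio matrix and Y the zone's one-hot mask, restricted
to pixels where the ratio is defined (405 nm intensity strictly above the
validity threshold, default 0).  Group contrasts use Welch's unequal-
variance t-test with Welch–Satterthwaite degrees of freedom; no multiple-
testing correction is applied (raw statistics are reported, flagged in the
report as multiple comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import CLASS_NAMES, MultiChannelImage, SampleRecord, SegmentationMask

__all__ = [
    "RatioImage",
    "ZoneMeasure",
    "GroupComparison",
    "compute_ratio_image",
    "zone_mean_ratio",
    "welch_t_test",
    "group_statistics",
    "measures_frame",
    "comparisons_frame",
]

ZONES_OF_INTEREST = ("root", "EEZ", "LEZ", "MZ")


@dataclass
class RatioImage:
    """Per-pixel 458/405 ratio with a validity mask."""

    X: np.ndarray  # (H, W) float32, 0 where invalid
    valid: np.ndarray  # (H, W) bool


@dataclass
class ZoneMeasure:
    """Mean ratio of one zone in one sample (NaN when no valid zone pixel)."""

    sample_id: str
    zone: str
    mean_ratio: float
    n_pixels: int

    @property
    def missing(self) -> bool:
        return self.n_pixels == 0


@dataclass
class GroupComparison:
    zone: str
    group_a: tuple  # (line, treatment)
    group_b: tuple
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    summary_a: dict
    summary_b: dict


def compute_ratio_image(
    image: MultiChannelImage, denominator_eps: float = 0.0
) -> RatioImage:
    """X = fl458 / fl405 per pixel; pixels with fl405 ≤ eps are invalid."""
    fl405 = image.channel("fl405").astype(np.float64)
    fl458 = image.channel("fl458").astype(np.float64)
    valid = fl405 > denominator_eps
    X = np.zeros(fl405.shape, dtype=np.float32)
    np.divide(fl458, fl405, out=X, where=valid, casting="unsafe")
    return RatioImage(X=X, valid=valid)


def zone_mean_ratio(
    ratio: RatioImage,
    mask: SegmentationMask | np.ndarray,
    zone: str | int,
    sample_id: str = "",
) -> ZoneMeasure:
    """Masked mean of the ratio over valid pixels of one zone."""
    labels = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    if labels.shape != ratio.X.shape:
        raise ValueError("mask and ratio image shapes differ")
    if isinstance(zone, str):
        if zone not in CLASS_NAMES:
            raise ValueError(f"unknown zone {zone!r}")
        zone_id, zone_name = CLASS_NAMES.index(zone), zone
    else:
        zone_id, zone_name = int(zone), CLASS_NAMES[int(zone)]
    select = (labels == zone_id) & ratio.valid
    n = int(select.sum())
    mean = float(ratio.X[select].mean()) if n else float("nan")
    return ZoneMeasure(sample_id=sample_id, zone=zone_name, mean_ratio=mean, n_pixels=n)


def welch_t_test(values_a, values_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, df, two-sided p)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    for name, v in (("a", a), ("b", b)):
        if v.size < 2 or not np.all(np.isfinite(v)):
            raise ValueError(f"group {name} needs >= 2 finite values")
        if np.var(v, ddof=1) == 0:
            raise ValueError(f"group {name} has zero variance")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.df), float(result.pvalue)


def _summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def default_comparisons(
    groups: list[tuple], reference_line: str = "Col-0", control_treatment: str = "mock"
) -> list[tuple]:
    """Treatment contrast within each line; line-vs-reference within each treatment."""
    lines = sorted({g[0] for g in groups})
    treatments = sorted({g[1] for g in groups})
    comparisons = []
    for line in lines:
        others = [t for t in treatments if t != control_treatment]
        for t in others:
            if (line, control_treatment) in groups and (line, t) in groups:
                comparisons.append(((line, control_treatment), (line, t)))
    for treatment in treatments:
        for line in lines:
            if line == reference_line:
                continue
            if (reference_line, treatment) in groups and (line, treatment) in groups:
                comparisons.append(((reference_line, treatment), (line, treatment)))
    return comparisons


def group_statistics(
    measures: list[ZoneMeasure],
    records: list[SampleRecord],
    comparisons: list[tuple] | None = None,
    reference_line: str = "Col-0",
    control_treatment: str = "mock",
) -> list[GroupComparison]:
    """Run configured group contrasts per zone over per-sample zone means."""
    by_id = {r.sample_id: r for r in records}
    rows = []
    for m in measures:
        if m.sample_id not in by_id:
            raise ValueError(f"measure for unknown sample {m.sample_id!r}")
        if m.missing or not np.isfinite(m.mean_ratio):
            continue
        rec = by_id[m.sample_id]
        rows.append((m.zone, rec.line, rec.treatment, m.mean_ratio))
    frame = pd.DataFrame(rows, columns=["zone", "line", "treatment", "mean_ratio"])
    groups = sorted(
        {(line, tr) for line, tr in zip(frame["line"], frame["treatment"])}
    )
    if comparisons is None:
        comparisons = default_comparisons(
            groups, reference_line=reference_line, control_treatment=control_treatment
        )
    for ga, gb in comparisons:
        if tuple(ga) not in groups or tuple(gb) not in groups:
            raise ValueError(f"comparison {ga} vs {gb} references unknown groups")
    out: list[GroupComparison] = []
    for zone in sorted(frame["zone"].unique(), key=CLASS_NAMES.index):
        zframe = frame[frame["zone"] == zone]
        for ga, gb in comparisons:
            va = zframe.query("line == @ga[0] and treatment == @ga[1]")["mean_ratio"]
            vb = zframe.query("line == @gb[0] and treatment == @gb[1]")["mean_ratio"]
            if len(va) < 2 or len(vb) < 2:
                continue
            t, df, p = welch_t_test(va.to_numpy(), vb.to_numpy())
            out.append(
                GroupComparison(
                    zone=zone,
                    group_a=tuple(ga),
                    group_b=tuple(gb),
                    t_statistic=t,
                    degrees_of_freedom=df,
                    p_value=p,
                    summary_a=_summary(va.to_numpy()),
                    summary_b=_summary(vb.to_numpy()),
                )
            )
    return out


def measures_frame(
    measures: list[ZoneMeasure], records: list[SampleRecord]
) -> pd.DataFrame:
    """Per-sample zone measures as a tidy table for CSV export."""
    by_id = {r.sample_id: r for r in records}
    rows = []
    for m in measures:
        rec = by_id.get(m.sample_id)
        rows.append(
            {
                "sample_id": m.sample_id,
                "line": rec.line if rec else "",
                "treatment": rec.treatment if rec else "",
                "zone": m.zone,
                "mean_ratio": m.mean_ratio,
                "n_pixels": m.n_pixels,
            }
        )
    return pd.DataFrame(rows)


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "zone": c.zone,
                "group_a": f"{c.group_a[0]}:{c.group_a[1]}",
                "group_b": f"{c.group_b[0]}:{c.group_b[1]}",
                "t_statistic": c.t_statistic,
                "df": c.degrees_of_freedom,
                "p_value": c.p_value,
                "n_a": c.summary_a["n"],
                "mean_a": c.summary_a["mean"],
                "median_a": c.summary_a["median"],
                "q1_a": c.summary_a["q1"],
                "q3_a": c.summary_a["q3"],
                "n_b": c.summary_b["n"],
                "mean_b": c.summary_b["mean"],
                "median_b": c.summary_b["median"],
                "q1_b": c.summary_b["q1"],
                "q3_b": c.summary_b["q3"],
            }
        )
    return pd.DataFrame(rows)
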