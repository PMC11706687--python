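"""Self-contained HTML report: per-sample panels plus statistics tables.

Rendered with plain string templates and matplotlib figures embedded as
base64 PNG data URIs, so the document opens without network access.
"""

from __future__ import annotations

import base64
import html
import io
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from .image_io import CLASS_NAMES

__all__ = ["render_report", "sample_panel_figure"]

_ZONE_COLORS = ListedColormap(["#30409f", "#e8c84b", "#56a056", "#9c5c32", "#8a4f9e"])


def _fig_to_data_uri(fig) -> str:
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90, bbox_inches="tight")
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def sample_panel_figure(
    brightfield: np.ndarray,
    segmentation: np.ndarray,
    ratio: np.ndarray,
    uncertainty: np.ndarray | None = None,
    attributions: dict | None = None,
):
    """One figure per sample: input, segmentation, ratio, uncertainty, attribution."""
    attributions = attributions or {}
    n = 3 + (uncertainty is not None) + len(attributions)
    fig, axes = plt.subplots(1, n, figsize=(2.6 * n, 2.8))
    axes = np.atleast_1d(axes)
    axes[0].imshow(brightfield, cmap="gray")
    axes[0].set_title("bf-405nm", fontsize=8)
    axes[1].imshow(segmentation, cmap=_ZONE_COLORS, vmin=0, vmax=4, interpolation="nearest")
    axes[1].set_title("segmentation", fontsize=8)
    im = axes[2].imshow(ratio, cmap="magma")
    axes[2].set_title("458/405 ratio", fontsize=8)
    fig.colorbar(im, ax=axes[2], fraction=0.046)
    k = 3
    if uncertainty is not None:
        # dark = low, bright = high uncertainty
        im = axes[k].imshow(uncertainty, cmap="viridis")
        axes[k].set_title("MC-dropout std", fontsize=8)
        fig.colorbar(im, ax=axes[k], fraction=0.046)
        k += 1
    for cid, attr in attributions.items():
        scale = np.abs(attr).max() or 1.0
        axes[k].imshow(np.abs(attr) / scale, cmap="Oranges", vmin=0, vmax=1)
        axes[k].set_title(f"GGC {CLASS_NAMES[cid]}", fontsize=8)
        k += 1
    for ax in axes:
        ax.set_xticks([])
        ax.set_yticks([])
    return fig


def _table_html(frame: pd.DataFrame, caption: str) -> str:
    if frame.empty:
        return f"<h3>{html.escape(caption)}</h3><p>(no rows)</p>"
    return f"<h3>{html.escape(caption)}</h3>" + frame.to_html(
        index=False, float_format=lambda v: f"{v:.4g}", border=0
    )


_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
table {{ border-collapse: collapse; font-size: 13px; }}
td, th {{ padding: 3px 9px; border-bottom: 1px solid #ccc; text-align: right; }}
th {{ background: #f0f0f0; }}
.panel {{ margin-bottom: 1.2em; }}
.note {{ color: #777; font-size: 12px; }}
</style></head>
<body>
<h1>{title}</h1>
<p class="note">{subtitle}</p>
{stats}
<h2>Per-sample panels</h2>
{panels}
</body></html>
"""


def render_report(
    out_path: str | Path,
    measures: pd.DataFrame,
    comparisons: pd.DataFrame,
    panels: list[tuple[str, str]],
    title: str = "Root-zone ratiometric analysis",
    manifest_note: str = "",
) -> Path:
    """Write the HTML report.

    ``panels`` is a list of (sample_id, data-uri) pairs; statistics tables
    are embedded as HTML.  Raw Welch p-values are reported for multiple
    zones and contrasts without correction, as flagged below.
    """
    stats = _table_html(measures, "Per-sample zone mean ratios")
    stats += _table_html(comparisons, "Welch's t-test group comparisons")
    stats += (
        "<p class='note'>p-values are two-sided and uncorrected; several zones "
        "and contrasts are tested simultaneously.</p>"
    )
    panel_html = "\n".join(
        f"<div class='panel'><b>{html.escape(sid)}</b><br>"
        f"<img src='{uri}' alt='{html.escape(sid)}'></div>"
        for sid, uri in panels
    )
    out_path = Path(out_path)
    out_path.write_text(
        _PAGE.format(
            title=html.escape(title),
            subtitle=html.escape(manifest_note),
            stats=stats,
            panels=panel_html,
        )
    )
    return out_path
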