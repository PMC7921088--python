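"""Panel figures of bias by registration-error combination.

The figure grammar mirrors the study's summary plots: one panel per
timepoint (or per Factor-X stratum), scenarios side by side on the x axis
grouped by the missed-case probability and the relative risk of being
missed, marker colour distinguishing the trace-back probability and
marker shape the wrong-date setting.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_TRACE_COLORS = {0.7: "tab:blue", 0.9: "tab:orange"}
_WRONG_MARKERS = {0.0: "o", 0.3: "^"}


def _panel(ax, df: pd.DataFrame) -> None:
    scenarios = sorted(df["scenario_id"].unique())
    p_miss_levels = sorted(df["p_miss"].unique())
    rr_levels = sorted(df["rr_miss_x"].unique())
    # x position: (p_miss, rr) blocks, scenarios within a block
    block_keys = [(pm, rr) for pm in p_miss_levels for rr in rr_levels]
    width = len(scenarios) + 1
    ticks, labels = [], []
    for b, (pm, rr) in enumerate(block_keys):
        ticks.append(b * width + (len(scenarios) - 1) / 2)
        labels.append(f"{pm:g}\nRR {rr:g}")
        for s_i, sid in enumerate(scenarios):
            sub = df[(df["p_miss"] == pm) & (df["rr_miss_x"] == rr)
                     & (df["scenario_id"] == sid)]
            for _, row in sub.iterrows():
                ax.plot(
                    b * width + s_i,
                    row["mean_bias"],
                    marker=_WRONG_MARKERS.get(row["p_wrong_date"], "s"),
                    color=_TRACE_COLORS.get(row["p_trace"], "tab:gray"),
                    linestyle="none",
                    markersize=5,
                )
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_xlabel("probability missed / RR missed if Factor X")
    ax.set_ylabel("bias (percentage points)")
    ax.axhline(0.0, color="0.7", lw=0.8)


def plot_bias_panels(summary: pd.DataFrame, outdir, stratify: str | None = None,
                     basename: str = "bias_panels") -> list[Path]:
    """Write bias panel figures (PDF + PNG) from a bias summary table.

    ``stratify=None`` panels by timepoint (overall stratum only);
    ``stratify="x"`` panels by Factor-X stratum at the first timepoint.
    Returns the written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stratify not in (None, "x"):
        raise ValueError("stratify must be None or 'x'")

    if stratify is None:
        df = summary[summary["stratum"] == "overall"]
        panels = [(f"{tp:g}-year net survival", df[df["timepoint"] == tp])
                  for tp in sorted(df["timepoint"].unique())]
    else:
        tp0 = sorted(summary["timepoint"].unique())[0]
        df = summary[(summary["timepoint"] == tp0)
                     & summary["stratum"].isin(["x=0", "x=1"])]
        panels = [(f"{tp0:g}-year net survival, {label}",
                   df[df["stratum"] == stratum])
                  for stratum, label in (("x=0", "without Factor X"),
                                         ("x=1", "with Factor X"))]

    fig, axes = plt.subplots(len(panels), 1,
                             figsize=(10, 3.2 * len(panels)), squeeze=False)
    for ax, (title, sub) in zip(axes.ravel(), panels):
        _panel(ax, sub)
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    paths = []
    for ext in ("pdf", "png"):
        p = outdir / f"{basename}.{ext}"
        fig.savefig(p, dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths
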