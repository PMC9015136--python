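"""Matplotlib adapters over module outputs.

Plots are thin views of the tested data structures; the numbers, not the
images, are the package's contract. Default class colors: disorder green,
order purple, neutral pink.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .disorder import CH_INTERCEPT, CH_SLOPE, INSOLUBLE_HYDROPATHY, ChargeHydropathyPoint, FoldIndexResult
from .profiles import Profile
from .seqmap import SequenceMapLayout
from .tendency import DISORDER_NEUTRAL, DISORDER_PROMOTING, MASKED_LABEL, ORDER_PROMOTING

CLASS_COLORS = {
    DISORDER_PROMOTING: "#2ca02c",  # green
    ORDER_PROMOTING: "#9467bd",  # purple
    DISORDER_NEUTRAL: "#e377c2",  # pink
    MASKED_LABEL: "#7f7f7f",
}


def charge_hydropathy_plot(points: list[ChargeHydropathyPoint], ax=None):
    """Scatter on the charge-hydropathy plane with boundary lines."""
    if ax is None:
        _, ax = plt.subplots()
    h = np.linspace(0.0, 1.0, 200)
    boundary = CH_SLOPE * h - CH_INTERCEPT
    ax.plot(h, boundary, "k--", lw=1)
    ax.plot(h, -boundary, "k--", lw=1)
    ax.axvline(INSOLUBLE_HYDROPATHY, color="red", lw=1, ls=":")
    for p in points:
        ax.scatter(p.mean_hydropathy, p.mean_net_charge, zorder=3)
        ax.annotate(p.label, (p.mean_hydropathy, p.mean_net_charge), fontsize=8)
    ax.set_xlabel("mean scaled hydropathy")
    ax.set_ylabel("mean net charge per residue")
    ax.set_xlim(0, 1)
    return ax


def profile_plot(profile: Profile, ax=None, **plot_kwargs):
    """Line plot of a windowed profile."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.positions, profile.values, **plot_kwargs)
    ax.set_xlabel("residue position")
    ax.set_ylabel(profile.name or "value")
    return ax


def foldindex_plot(result: FoldIndexResult, ax=None):
    """FoldIndex profile with the zero line and sign shading."""
    if ax is None:
        _, ax = plt.subplots()
    pos, val = result.profile.positions, result.profile.values
    ax.axhline(0.0, color="k", lw=0.8)
    ax.fill_between(pos, val, 0, where=val < 0, color="#d62728", alpha=0.4)
    ax.fill_between(pos, val, 0, where=val >= 0, color="#1f77b4", alpha=0.4)
    ax.plot(pos, val, color="k", lw=0.8)
    ax.set_xlabel("residue position")
    ax.set_ylabel("FoldIndex score")
    return ax


def tendency_plot(labels: list[str], ax=None):
    """Per-position structural tendency as colored bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    for i, label in enumerate(labels, start=1):
        ax.bar(i, 1.0, width=1.0, color=CLASS_COLORS.get(label, "#7f7f7f"))
    ax.set_yticks([])
    ax.set_xlabel("residue position")
    return ax


def sequence_map_plot(layout: SequenceMapLayout, ax=None, cmap: str = "viridis"):
    """Grid rendering of a sequence map (discrete or continuous values)."""
    if ax is None:
        _, ax = plt.subplots()
    values = [c.value for c in layout.cells]
    continuous = all(isinstance(v, (int, float)) and not isinstance(v, bool) for v in values)
    if continuous:
        vmin, vmax = min(values), max(values)
        span = (vmax - vmin) or 1.0
        mapper = plt.get_cmap(cmap)
        color_of = lambda v: mapper((v - vmin) / span)
    else:
        palette = CLASS_COLORS.copy()
        extra = [v for v in dict.fromkeys(values) if v not in palette]
        fallback = plt.get_cmap("tab10")
        for i, v in enumerate(extra):
            palette[v] = fallback(i % 10)
        color_of = palette.__getitem__
    for cell in layout.cells:
        ax.add_patch(
            plt.Rectangle(
                (cell.column - 1, -cell.row), 1, 1, color=color_of(cell.value)
            )
        )
        ax.text(
            cell.column - 0.5, -cell.row + 0.5, cell.residue,
            ha="center", va="center", fontsize=6,
        )
    for ann in layout.annotations:
        for pos in range(ann.start, ann.end + 1):
            cell = layout.cells[pos - 1]
            ax.add_patch(
                plt.Rectangle(
                    (cell.column - 1, -cell.row), 1, 1,
                    fill=False, edgecolor="black", lw=1.2,
                )
            )
    ax.set_xlim(0, layout.n_columns)
    ax.set_ylim(-layout.n_rows(), 0)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(layout.sequence_id, fontsize=8)
    return ax
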