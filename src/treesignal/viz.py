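"""Plots: traits along the phylogeny and correlograms.

``render_trait_plot`` draws the tree on the left (a rectangular layout
computed from node depths) and, per trait, a panel of bars, dots or
colored grid cells aligned with the tips; per-tip highlight flags (e.g.
significant local Moran values) are rendered in a highlight color.
``render_correlogram`` draws the autocorrelation curve with its dashed
bootstrap envelope, the no-signal reference line, and a significance
color bar (red positive / black none / blue negative by default).
Assertions in tests target the data layer (:func:`trait_layout`,
returned artists' coordinates), not pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # noqa: E402 -- headless backend before pyplot
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .correlogram import CorrelogramResult
from .treedata import Tree, TraitTree

__all__ = ["PlotData", "trait_layout", "render_trait_plot", "render_correlogram",
           "CLASS_COLORS"]

CLASS_COLORS = {"positive": "red", "none": "black", "negative": "blue"}


@dataclass
class PlotData:
    """Display-ready trait values aligned to the tree's tip order."""

    tip_order: list
    values: pd.DataFrame  # rows follow tip_order
    centered: bool
    scaled: bool
    means: pd.Series
    sds: pd.Series

    def inverse(self) -> pd.DataFrame:
        """Undo the recorded centering/scaling exactly."""
        out = self.values.copy()
        if self.scaled:
            out = out * self.sds
        if self.centered:
            out = out + self.means
        return out


def trait_layout(traittree: TraitTree, center: bool = True, scale: bool = True) -> PlotData:
    """Center/scale traits per column for display, tips in tree order."""
    values = traittree.traits.copy()
    if values.shape[1] < 1:
        raise ValueError("no traits to lay out")
    means = values.mean()
    sds = values.std(ddof=1)  # sample sd: (1,2,3) scales to (-1,0,1)
    if scale and (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"cannot scale constant traits: {bad}")
    if center:
        values = values - means
    if scale:
        values = values / sds
    return PlotData(
        tip_order=list(traittree.tree.tip_labels),
        values=values,
        centered=center,
        scaled=scale,
        means=means,
        sds=sds,
    )


def _tree_segments(tree: Tree):
    """Horizontal and vertical line segments of a rectangular tree layout;
    tip k sits at y = k (canonical order)."""
    depth = tree.node_depths()
    children = tree.children()
    ypos = np.zeros(tree.n_nodes)
    for k, t in enumerate(tree.tip_ids):
        ypos[t] = k
    for u in range(tree.n_nodes):
        if children[u]:
            ypos[u] = np.mean([ypos[c] for c in children[u]])
    hseg, vseg = [], []
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p >= 0:
            hseg.append(((depth[p], ypos[u]), (depth[u], ypos[u])))
    for u in range(tree.n_nodes):
        if children[u]:
            ys = [ypos[c] for c in children[u]]
            vseg.append(((depth[u], min(ys)), (depth[u], max(ys))))
    return hseg, vseg, depth, ypos


def render_trait_plot(
    plotdata: PlotData,
    tree: Tree,
    style: str = "bar",
    path=None,
    highlight=None,
    color: str = "grey",
    highlight_color: str = "red",
):
    """Draw tree + trait panels; returns the matplotlib Figure.

    ``highlight`` is an optional boolean sequence per tip (e.g.
    p < 0.05 from a LIPA run) rendered in ``highlight_color``.
    """
    if plotdata.values.shape[1] == 0:
        raise ValueError("no traits to plot")
    if list(plotdata.tip_order) != tree.tip_labels:
        raise ValueError("plot data is not aligned to this tree")
    if style not in ("bar", "dot", "grid"):
        raise ValueError(f"unknown style {style!r}")
    n = len(plotdata.tip_order)
    traits = list(plotdata.values.columns)
    flags = np.zeros(n, dtype=bool) if highlight is None else np.asarray(highlight, bool)
    colors = np.where(flags, highlight_color, color)

    fig, axes = plt.subplots(
        1, 1 + len(traits), sharey=True,
        figsize=(3 + 1.6 * len(traits), max(2.5, 0.28 * n)),
        gridspec_kw={"width_ratios": [2.2] + [1] * len(traits)},
    )
    axes = np.atleast_1d(axes)
    ax = axes[0]
    hseg, vseg, depth, _ = _tree_segments(tree)
    for (x0, y0), (x1, y1) in hseg + vseg:
        ax.plot([x0, x1], [y0, y1], color="black", lw=1)
    for k, lab in enumerate(plotdata.tip_order):
        ax.text(depth.max() * 1.02, k, lab, va="center", fontsize=7)
    ax.set_xlim(0, depth.max() * 1.45)
    ax.axis("off")

    for j, trait in enumerate(traits):
        axt = axes[1 + j]
        vals = plotdata.values[trait].to_numpy()
        if style == "bar":
            axt.barh(np.arange(n), vals, color=colors, height=0.7)
            axt.axvline(0, color="black", lw=0.6)
        elif style == "dot":
            axt.scatter(vals, np.arange(n), c=colors, s=18)
            axt.axvline(0, color="black", lw=0.6)
        else:  # grid
            axt.imshow(
                vals[:, None], aspect="auto", cmap="RdBu_r", origin="lower",
                extent=(-0.5, 0.5, -0.5, n - 0.5),
            )
        axt.set_title(trait, fontsize=8)
        axt.tick_params(labelleft=False, left=False)
    axes[0].set_ylim(-0.7, n - 0.3)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def render_correlogram(result: CorrelogramResult, path=None, colors=CLASS_COLORS):
    """Curve + dashed envelope + reference line + class color bar."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(result.grid, result.stat, color="black", lw=2, label="autocorrelation")
    if result.ci_lo is not None:
        ax.plot(result.grid, result.ci_lo, color="black", lw=1, ls="--")
        ax.plot(result.grid, result.ci_hi, color="black", lw=1, ls="--",
                label=f"{result.conf:.0%} envelope")
    ax.axhline(result.h0, color="black", lw=1)
    ymin = min(np.min(result.stat), result.h0) - 0.1
    for mu, cls in zip(result.grid, result.classes):
        ax.plot([mu], [ymin], marker="s", ms=4, color=colors[str(cls)])
    ax.set_xlabel("phylogenetic distance")
    ax.set_ylabel("Moran's I" if result.kind == "moran" else "Mantel statistic")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
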