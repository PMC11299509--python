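"""Figure helpers: fold-change panels, group bars and LCN overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .groupstats import GroupComparison
from .lcn2d import FieldAnalysis


def plot_fold_change_panel(panel: pd.DataFrame, ax=None):
    """Bar chart of per-gene fold changes with significance flags.

    ``panel`` is the (reference-excluded) output of
    :func:`osteolcn.qpcr.panel_report`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * len(panel), 3.2))
    x = np.arange(len(panel))
    ax.bar(x, panel["fold_change"], color="0.4")
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    for xi, (fc, stars) in enumerate(zip(panel["fold_change"], panel["stars"])):
        if stars and stars != "ns":
            ax.text(xi, fc * 1.05, stars, ha="center", va="bottom", fontsize=9)
    ax.set_xticks(x, panel.index, rotation=45, ha="right")
    ax.set_ylabel("fold change (2$^{-\\Delta\\Delta Ct}$)")
    ax.set_yscale("log", base=2)
    return ax


def plot_group_comparison(cmp: GroupComparison, a, b, ax=None):
    """Mean +/- SD bars with individual points and a star annotation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(2.4, 3.2))
    means = [cmp.mean_a, cmp.mean_b]
    sds = [cmp.sd_a, cmp.sd_b]
    ax.bar([0, 1], means, yerr=sds, capsize=4, color=["0.7", "0.35"])
    rng = np.random.default_rng(0)
    for i, vals in enumerate((a, b)):
        vals = np.asarray(vals, dtype=float)
        ax.plot(i + rng.uniform(-0.12, 0.12, vals.size), vals, "ko", ms=3, alpha=0.6)
    ax.set_xticks([0, 1], [cmp.group_a, cmp.group_b])
    ax.set_ylabel(cmp.metric)
    top = max(means[i] + sds[i] for i in range(2))
    ax.text(0.5, top * 1.05, cmp.stars, ha="center", fontsize=10)
    return ax


def plot_lcn_overlay(fa: FieldAnalysis, window_deg: float = 20.0, ax=None):
    """Overlay of the analyzed field: network components colored by
    alignment (aligned vs unaligned with the vertical) and lacuna bodies
    outlined; mirrors the orientation figures of silver-stain analyses."""
    from skimage.measure import label as sk_label

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    seg = fa.seg
    h, w = seg.network.shape
    rgb = np.ones((h, w, 3))
    labels = sk_label(seg.network, connectivity=2)
    otab = fa.orientation_table
    if otab is not None and len(otab):
        aligned = set(otab.loc[otab["aligned"], "label"])
        unaligned = set(otab.loc[~otab["aligned"], "label"])
        rgb[np.isin(labels, list(aligned))] = (0.1, 0.3, 0.9)
        rgb[np.isin(labels, list(unaligned))] = (0.9, 0.15, 0.1)
    rgb[seg.bodies] = (0.2, 0.2, 0.2)
    ax.imshow(rgb, interpolation="nearest")
    ax.set_axis_off()
    return ax
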