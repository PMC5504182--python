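"""Matplotlib figures for the standard outputs: OPLS-DA score plots,
covariance pseudo-spectra colored by r², SUS scatters, correlation-network
layouts and fold-change color tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "score_plot",
    "pseudospectrum_plot",
    "sus_scatter",
    "network_plot",
    "color_table_figure",
]


def score_plot(results, ax=None):
    """Predictive vs first orthogonal OPLS-DA scores, colored by class."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    t = results.scores_pred
    t_o = (
        results.ortho_scores[0]
        if results.n_orthogonal
        else np.zeros_like(t)
    )
    labels = np.asarray(results.model.labels)
    for lab, marker in zip(sorted(set(labels)), "osD^v"):
        m = labels == lab
        ax.scatter(t[m], t_o[m], label=str(lab), marker=marker, alpha=0.8)
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    ax.set_xlabel("t (predictive)")
    ax.set_ylabel("t_o (orthogonal)" if results.n_orthogonal else "")
    ax.set_title(f"OPLS-DA scores (R2Y={results.r2y:.2f})")
    ax.legend()
    return ax.figure


def pseudospectrum_plot(pseudo: pd.DataFrame, ax=None):
    """Covariance heights colored by squared correlation (blue 0 -> red 1)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = pseudo["ppm"]
    if x.isna().all():
        x = np.arange(len(pseudo))
        ax.set_xlabel("feature index")
    else:
        ax.set_xlabel("ppm")
        ax.invert_xaxis()
    sc = ax.scatter(x, pseudo["covariance"], c=pseudo["r2"], cmap="jet", vmin=0, vmax=1, s=8)
    ax.vlines(x, 0, pseudo["covariance"], color="lightgray", lw=0.5, zorder=0)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_ylabel("Cov(t_p, X)")
    ax.figure.colorbar(sc, ax=ax, label="r²")
    return ax.figure


def sus_scatter(sus: pd.DataFrame, ax=None):
    """Corr(tp,X) of model A against model B with category coloring."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    colors = {
        "shared-positive": "tab:red",
        "shared-negative": "tab:purple",
        "unique-A": "tab:blue",
        "unique-B": "tab:green",
        "not-significant": "lightgray",
    }
    for cat, sub in sus.groupby("category"):
        ax.scatter(sub["corr_A"], sub["corr_B"], label=cat, c=colors.get(cat, "k"), s=20)
    thr = sus.attrs.get("threshold", 0.5)
    for v in (-thr, thr):
        ax.axhline(v, color="gray", lw=0.5, ls="--")
        ax.axvline(v, color="gray", lw=0.5, ls="--")
    ax.plot([-1, 1], [-1, 1], color="red", lw=0.5)
    ax.plot([-1, 1], [1, -1], color="blue", lw=0.5)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel(f"Corr(tp,X): {sus.attrs.get('class_A', 'A')}")
    ax.set_ylabel(f"Corr(tp,X): {sus.attrs.get('class_B', 'B')}")
    ax.legend(fontsize=7)
    return ax.figure


def network_plot(net: nx.Graph, ax=None, seed: int = 0):
    """Spring-layout rendering with |r|-scaled widths and diverging colors."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    pos = nx.spring_layout(net, seed=seed)
    widths = [3 * d.get("width", 1) for _, _, d in net.edges(data=True)]
    colors = [d.get("color", "gray") for _, _, d in net.edges(data=True)]
    node_colors = [
        "tab:red" if net.nodes[n].get("direction") == "increased"
        else "tab:blue" if net.nodes[n].get("direction") == "decreased"
        else "lightgray"
        for n in net.nodes
    ]
    nx.draw_networkx(
        net, pos=pos, ax=ax, width=widths, edge_color=colors,
        node_color=node_colors, node_size=120, font_size=6,
    )
    ax.set_axis_off()
    return ax.figure


def color_table_figure(colored: pd.DataFrame, ax=None):
    """Render a fold-change color table (one row per feature) as a figure."""
    comps = list(colored.columns.get_level_values(0).unique())
    features = list(colored.index)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(comps) + 2, 0.22 * len(features) + 1))
    for j, comp in enumerate(comps):
        block = colored[comp]
        for i, feat in enumerate(features):
            ax.add_patch(
                plt.Rectangle((j, len(features) - 1 - i), 1, 1,
                              facecolor=block.loc[feat, "color"], edgecolor="white")
            )
            ax.text(
                j + 0.5, len(features) - 0.5 - i,
                f"{block.loc[feat, 'FC']:.2g}{block.loc[feat, 'stars']}",
                ha="center", va="center", fontsize=6,
            )
    ax.set_xlim(0, len(comps))
    ax.set_ylim(0, len(features))
    ax.set_xticks(np.arange(len(comps)) + 0.5, comps, fontsize=7)
    ax.set_yticks(np.arange(len(features)) + 0.5, features[::-1], fontsize=6)
    return ax.figure
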