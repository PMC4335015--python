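"""Figure rendering: diversity bars, EHH curves, bifurcation diagrams."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .hapio import CoreVariant

_CLASS_COLORS = {
    "derived": "black",
    "melanistic": "black",
    "ancestral": "#d4a017",
    "non_melanistic": "#d4a017",
}


def plot_diversity_profile(df: pd.DataFrame, path: str | Path) -> None:
    """Grouped bar chart of per-window pi (in percent) with SEM error bars."""
    windows = list(dict.fromkeys(df["window"]))
    classes = list(dict.fromkeys(df["class"]))
    x = np.arange(len(windows))
    width = 0.8 / len(classes)
    fig, ax = plt.subplots(figsize=(max(6, len(windows)), 4))
    for k, cls in enumerate(classes):
        sub = df[df["class"] == cls].set_index("window").reindex(windows)
        ax.bar(
            x + (k - (len(classes) - 1) / 2) * width,
            sub["pi_percent"],
            width,
            yerr=sub["sem"] * 100,
            capsize=2,
            label=cls,
            color=_CLASS_COLORS.get(cls, None),
            edgecolor="black",
            linewidth=0.4,
        )
    ax.set_xticks(x, windows, rotation=45, ha="right")
    ax.set_ylabel("nucleotide diversity (%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ehh(ehh_df: pd.DataFrame, core: CoreVariant, path: str | Path) -> None:
    """EHH of both classes against genomic position, core marked in red."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for direction in ("upstream", "downstream"):
        sub = ehh_df[ehh_df["direction"] == direction].sort_values("pos")
        ax.plot(sub["pos"], sub["ehh_derived"], color="black",
                label="derived" if direction == "upstream" else None)
        ax.plot(sub["pos"], sub["ehh_ancestral"], color="grey",
                label="ancestral" if direction == "upstream" else None)
    ax.axvline(core.pos, color="red", linewidth=1)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("EHH")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _draw_tree(ax, tree_dict: dict, sign: int) -> None:
    """Recursive layout: x = site order away from core, y spread per split,
    line width proportional to chromosome count."""
    root = tree_dict["tree"]
    n = root["count"]

    def rec(node: dict, x: float, y: float, spread: float) -> None:
        kids = [node["children"][k] for k in sorted(node["children"])]
        offsets = (
            [0.0] if len(kids) < 2 else [-spread / 2, spread / 2]
        )
        for child, dy in zip(kids, offsets):
            ax.plot(
                [x, x + sign], [y, y + dy],
                color="black", solid_capstyle="round",
                linewidth=max(0.4, 6.0 * child["count"] / n),
            )
            rec(child, x + sign, y + dy, spread / 2)

    rec(root, 0.0, 0.0, 1.0)


def plot_bifurcation_pair(
    upstream: dict, downstream: dict, path: str | Path
) -> None:
    """Two-sided bifurcation diagram with the core at x = 0."""
    fig, ax = plt.subplots(figsize=(8, 4))
    _draw_tree(ax, upstream, sign=-1)
    _draw_tree(ax, downstream, sign=+1)
    ax.axvline(0, color="red", linewidth=1)
    ax.set_yticks([])
    ax.set_xlabel("sites from core (upstream <- 0 -> downstream)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
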