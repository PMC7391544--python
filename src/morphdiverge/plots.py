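"""Figure helpers for the three pipeline stages."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .types import DIET_CATEGORIES


def shape_difference_plot(means: dict, path: str | Path, scale: float = 2.0) -> None:
    """Overlay per-group mean shapes with displacement arrows (exaggerated)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = list(means)
    colors = {groups[0]: "0.55", groups[-1]: "black"}
    for g in groups:
        m = means[g]
        ax.plot(m[:, 0], m[:, 1], "o", ms=4, color=colors.get(g, "tab:blue"), label=str(g))
    if len(groups) == 2:
        a, b = means[groups[0]], means[groups[1]]
        for i in range(a.shape[0]):
            ax.annotate(
                "",
                xy=a[i] + scale * (b[i] - a[i]),
                xytext=a[i],
                arrowprops=dict(arrowstyle="->", lw=0.8, color="tab:red"),
            )
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def diet_composition_plot(w_pct: dict[str, pd.Series], path: str | Path) -> None:
    """Stacked bars of W% per category for each morph."""
    fig, ax = plt.subplots(figsize=(5, 4))
    morphs = list(w_pct)
    bottoms = np.zeros(len(morphs))
    cmap = plt.get_cmap("tab10")
    for ci, cat in enumerate(DIET_CATEGORIES):
        vals = np.array([float(w_pct[m].get(cat, 0.0)) for m in morphs])
        ax.bar(morphs, vals, bottom=bottoms, label=cat, color=cmap(ci))
        bottoms += vals
    ax.set_ylabel("wet-weight percentage (W%)")
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def growth_curves_plot(observations: pd.DataFrame, fits: dict, path: str | Path) -> None:
    """Back-calculated age-length scatter with fitted VBGF curves."""
    from .growth import vbgf

    fig, ax = plt.subplots(figsize=(6, 4))
    t_grid = np.linspace(
        observations["age"].min() - 0.5, observations["age"].max() + 0.5, 200
    )
    group_col = "morph" if "morph" in observations.columns else "sex"
    for i, (g, fit) in enumerate(fits.items()):
        sub = observations[observations[group_col] == g]
        color = f"C{i}"
        ax.plot(sub["age"], sub["length_mm"], ".", ms=3, alpha=0.35, color=color)
        ax.plot(
            t_grid,
            vbgf(t_grid, fit.l_inf, fit.k, fit.t0),
            color=color,
            label=f"{g}: L∞={fit.l_inf:.0f} mm, k={fit.k:.3f}/yr",
        )
    ax.set_xlabel("age (years)")
    ax.set_ylabel("back-calculated SL (mm)")
    ax.legend(frameon=False, fontsize=8)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
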