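"""Figures: ternary composition plots and darkness-by-exposure panels.

Ternary orientation follows the study convention: 100 % black at the
apex, 100 % yellow at the lower-left vertex, 100 % clear at the
lower-right vertex, so points drifting away from the lower-right corner
are larvae gaining chromatophore cover.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ambycolor import coda

__all__ = ["ternary_figure", "darkness_by_time_figure"]

_PAIRING_COLORS = {
    ("barbouri", "barbouri"): "#2d2d2d",
    ("barbouri", "texanum"): "#7b3294",
    ("texanum", "barbouri"): "#c2a5cf",
    ("texanum", "texanum"): "#d7a51c",
}


def _draw_triangle(ax):
    v = np.vstack([coda.TERNARY_VERTICES, coda.TERNARY_VERTICES[0]])
    ax.plot(v[:, 0], v[:, 1], color="k", lw=1)
    labels = ["black", "yellow", "clear"]
    offsets = [(0, 0.04), (-0.04, -0.05), (0.04, -0.05)]
    for (x, y), lab, (dx, dy) in zip(coda.TERNARY_VERTICES, labels, offsets):
        ax.text(x + dx, y + dy, lab, ha="center", va="center", fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")


def ternary_figure(
    observations: pd.DataFrame,
    path=None,
    means: pd.DataFrame | None = None,
    title: str = "",
):
    """Scatter compositions on a ternary plot, one panel per exposure level.

    `observations` needs count columns and the design factors; `means`
    (optional) are overlaid as squares, e.g. posterior cell means with
    ``p_black/p_yellow/p_clear`` columns.
    """
    levels = sorted(observations["exposure_h"].unique())
    fig, axes = plt.subplots(
        1, len(levels), figsize=(3.2 * len(levels), 3.4), squeeze=False
    )
    for ax, h in zip(axes[0], levels):
        _draw_triangle(ax)
        sub = observations[observations["exposure_h"] == h]
        p = coda.close(sub[["n_black", "n_yellow", "n_clear"]].to_numpy())
        xy = coda.ternary_coords(p)
        colors = [
            _PAIRING_COLORS.get((m, f), "gray")
            for m, f in zip(sub["mother"], sub["father"])
        ]
        ax.scatter(xy[:, 0], xy[:, 1], s=8, c=colors, alpha=0.6, lw=0)
        if means is not None:
            msub = means[means["exposure_h"] == h]
            mp = msub[["p_black", "p_yellow", "p_clear"]].to_numpy()
            mxy = coda.ternary_coords(mp / mp.sum(axis=1, keepdims=True))
            mcol = [
                _PAIRING_COLORS.get((m, f), "gray")
                for m, f in zip(msub["mother"], msub["father"])
            ]
            ax.scatter(
                mxy[:, 0], mxy[:, 1], marker="s", s=45, c=mcol,
                edgecolors="white", lw=0.8, zorder=3,
            )
        ax.set_title(f"{h} h", fontsize=10)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def darkness_by_time_figure(
    observations: pd.DataFrame,
    path=None,
    predictions: pd.DataFrame | None = None,
):
    """Darkness against exposure time per mother x father pairing.

    Observations are jittered points; `predictions` (per-cell posterior
    mean + HDCI from the darkness model) are drawn as lines with ribbons.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(0)
    levels = sorted(observations["exposure_h"].unique())
    xmap = {h: i for i, h in enumerate(levels)}
    for (m, f), sub in observations.groupby(["mother", "father"]):
        x = sub["exposure_h"].map(xmap) + rng.uniform(-0.18, 0.18, len(sub))
        ax.scatter(
            x, sub["darkness"], s=8, alpha=0.45, lw=0,
            color=_PAIRING_COLORS.get((m, f), "gray"),
            label=f"{m[0].upper()}x{f[0].upper()}",
        )
    if predictions is not None:
        for (m, f), sub in predictions.groupby(["mother", "father"]):
            sub = sub.sort_values("exposure_h")
            x = sub["exposure_h"].map(xmap)
            c = _PAIRING_COLORS.get((m, f), "gray")
            ax.plot(x, sub["mean"], color=c, lw=1.5)
            ax.fill_between(
                x, sub["hdci_low"], sub["hdci_high"], color=c, alpha=0.2, lw=0
            )
    ax.set_xticks(list(xmap.values()), [f"{h} h" for h in levels])
    ax.set_ylim(0, 1)
    ax.set_xlabel("UVR exposure")
    ax.set_ylabel("skin darkness")
    ax.legend(fontsize=7, ncol=2, title="mother x father", title_fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
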