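"""Matplotlib views of the radial plane and polar overlays.

Kept deliberately small: a scatter of survivors in the type-vs-intensity
plane and a polar bin overlay where circle size is the bin count and color
the mean outcome.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .radial import PolarBinGrid


def radial_scatter(points: pd.DataFrame, color=None, ax=None, **scatter_kw):
    """Scatter survivors at (x, y); distance from origin = intensity."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(points["x"], points["y"], c=color, s=scatter_kw.pop("s", 12),
               **scatter_kw)
    lim = 1.05
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.axhline(0, lw=0.5, color="0.8")
    ax.axvline(0, lw=0.5, color="0.8")
    ax.set_xlabel("x = intensity * cos(type angle)")
    ax.set_ylabel("y = intensity * sin(type angle)")
    return ax


def polar_bin_plot(grid: PolarBinGrid, ax=None, cmap="Reds"):
    """Circles on the polar lattice: size = count, color = mean outcome."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    t = grid.table[grid.table["count"] > 0]
    spec = grid.spec
    ang = (t["angle_bin"] + 0.5) / spec.n_angle * spec.angle_max
    rad = (t["radius_bin"] + 0.5) / spec.n_radius
    x, y = rad * np.cos(ang), rad * np.sin(ang)
    sizes = 200 * t["count"] / max(t["count"].max(), 1)
    sc = ax.scatter(x, y, s=sizes, c=t["mean_outcome"], cmap=cmap,
                    edgecolors="0.4", linewidths=0.5)
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label="mean outcome score")
    return ax
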