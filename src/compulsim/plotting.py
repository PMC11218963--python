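"""Figure-data visualizations (severity curves and the cost simplex).

These helpers plot the CSV-level outputs of :mod:`compulsim.stats`; the
aesthetics are intentionally minimal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_severity_curves", "plot_cost_simplex"]


def plot_severity_curves(curves, ax=None, metric: str = "pct_compulsive"):
    """Line plot of one binned severity metric against the distortion axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curves["bin_center"], curves[metric], marker="o")
    ax.set_xlabel("belief distortion (agent − world)")
    ax.set_ylabel(metric)
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    return ax


def plot_cost_simplex(coords, ax=None, color_by_type: bool = True):
    """Scatter of agents' normalized subjective costs on the 2-simplex.

    Barycentric layout: checking (right), washing (left), sickness (top).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    zc = coords["z_check"].to_numpy(float)
    zw = coords["z_wash"].to_numpy(float)
    zs = coords["z_sickness"].to_numpy(float)
    x = zc + 0.5 * zs
    y = zs * np.sqrt(3) / 2.0
    if color_by_type and "compulsion_type" in coords:
        palette = {
            "none": "lightgray",
            "pure_wash": "tab:blue",
            "pure_check": "tab:red",
            "mixed": "tab:purple",
        }
        colors = coords["compulsion_type"].map(palette).fillna("black")
    else:
        colors = "gray"
    ax.scatter(x, y, s=6, c=colors, alpha=0.6, linewidths=0)
    tri = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    ax.text(-0.02, -0.03, "wash", ha="right")
    ax.text(1.02, -0.03, "check", ha="left")
    ax.text(0.5, np.sqrt(3) / 2 + 0.03, "sickness", ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
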