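"""Optional ternary scatter of balance calls (matplotlib, lazy import)."""

from __future__ import annotations

import math
from typing import Sequence

from .classify import CENTROIDS, BalanceCall, ternary_xy

__all__ = ["plot_ternary"]

_VERTICES = {"A": (0.0, 0.0), "B": (1.0, 0.0), "D": (0.5, math.sqrt(3) / 2)}


def plot_ternary(
    calls: Sequence[BalanceCall],
    path=None,
    sizes: Sequence[float] | None = None,
    ax=None,
):
    """Scatter balance calls inside the reference triangle.

    ``sizes`` (e.g. log2 total expression) scale the symbol areas, mirroring
    the convention that symbol size tracks total triad expression. Returns the
    matplotlib Axes; writes to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    tri_x = [_VERTICES[v][0] for v in ("A", "B", "D", "A")]
    tri_y = [_VERTICES[v][1] for v in ("A", "B", "D", "A")]
    ax.plot(tri_x, tri_y, color="black", lw=1)
    for name, (vx, vy) in _VERTICES.items():
        ax.annotate(name, (vx, vy), textcoords="offset points", xytext=(0, 6), ha="center")
    for name, pos in CENTROIDS.items():
        cx, cy = ternary_xy(pos)
        ax.plot(cx, cy, marker="+", color="grey", ms=6)
    xs = [c.ternary_xy[0] for c in calls]
    ys = [c.ternary_xy[1] for c in calls]
    if sizes is not None:
        s = [max(float(v), 0.1) * 12 for v in sizes]
    else:
        s = 40
    ax.scatter(xs, ys, s=s, alpha=0.7, edgecolor="black", linewidths=0.5)
    for c in calls:
        if c.gene_name:
            ax.annotate(
                c.gene_name, c.ternary_xy, textcoords="offset points", xytext=(4, 4), fontsize=7
            )
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
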