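"""Seven-category balance classification on the expression simplex.

A triad's relative subgenome expression (fA, fB, fD) is a point on the
2-simplex. Following the seven-archetype scheme used for genome-wide wheat
triad analyses, each point is assigned to the nearest of seven idealised
centroids by Euclidean distance in the raw 3-D fraction space:

========== =====================
balanced    (1/3, 1/3, 1/3)
X dominant  1 at X, 0 elsewhere
X suppressed 0 at X, 1/2 at each other
========== =====================

Points close to more than one centroid (within ``epsilon`` of the minimal
distance) get every near-minimal centroid recorded in their boundary set, so
that calls "on the boundary" of several categories are surfaced rather than
hidden. Ternary plot coordinates use vertices A=(0,0), B=(1,0),
D=(1/2, sqrt(3)/2): x = fB + fD/2, y = fD*sqrt(3)/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .aggregate import SubgenomeExpression

__all__ = [
    "CENTROIDS",
    "CATEGORY_ORDER",
    "BalanceCall",
    "SimplexError",
    "classify",
    "ternary_xy",
    "classify_table",
]


class SimplexError(ValueError):
    """Fractions do not lie on the probability simplex."""


# Fixed order doubles as the deterministic tie-break: balanced first, then
# dominants A, B, D, then suppresseds A, B, D.
CATEGORY_ORDER: tuple[str, ...] = (
    "balanced",
    "A_dominant",
    "B_dominant",
    "D_dominant",
    "A_suppressed",
    "B_suppressed",
    "D_suppressed",
)

CENTROIDS: Mapping[str, tuple[float, float, float]] = {
    "balanced": (1 / 3, 1 / 3, 1 / 3),
    "A_dominant": (1.0, 0.0, 0.0),
    "B_dominant": (0.0, 1.0, 0.0),
    "D_dominant": (0.0, 0.0, 1.0),
    "A_suppressed": (0.0, 0.5, 0.5),
    "B_suppressed": (0.5, 0.0, 0.5),
    "D_suppressed": (0.5, 0.5, 0.0),
}

_SUM_TOL = 1e-6


def _check_simplex(fractions: Sequence[float]) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,):
        raise SimplexError("fractions must be a triple (fA, fB, fD)")
    if (f < -1e-12).any():
        raise SimplexError(f"fractions must be non-negative, got {tuple(f)}")
    if abs(f.sum() - 1.0) > _SUM_TOL:
        raise SimplexError(f"fractions must sum to 1 within {_SUM_TOL}, got sum {f.sum()!r}")
    return f


@dataclass(frozen=True)
class BalanceCall:
    """A classified fraction triple with distances to all seven centroids."""

    fractions: tuple[float, float, float]
    category: str
    distances: dict[str, float]
    boundary_set: tuple[str, ...]
    ternary_xy: tuple[float, float]
    gene_name: str | None = None
    context: tuple[str, str] | None = None


def classify(
    fractions: Sequence[float],
    epsilon: float = 0.05,
    gene_name: str | None = None,
    context: tuple[str, str] | None = None,
) -> BalanceCall:
    """Nearest-centroid balance call for a simplex point.

    ``epsilon`` is the fraction-space distance margin for the boundary set:
    every centroid whose distance exceeds the minimum by at most epsilon is
    recorded. Ties in the minimum are broken by the fixed centroid order.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    f = _check_simplex(fractions)
    distances = {
        name: float(np.linalg.norm(f - np.asarray(CENTROIDS[name])))
        for name in CATEGORY_ORDER
    }
    dmin = min(distances.values())
    category = next(n for n in CATEGORY_ORDER if distances[n] == dmin)
    boundary = tuple(n for n in CATEGORY_ORDER if distances[n] - dmin <= epsilon)
    return BalanceCall(
        fractions=(float(f[0]), float(f[1]), float(f[2])),
        category=category,
        distances=distances,
        boundary_set=boundary,
        ternary_xy=ternary_xy(f),
        gene_name=gene_name,
        context=context,
    )


def ternary_xy(fractions: Sequence[float]) -> tuple[float, float]:
    """Barycentric → Cartesian: A=(0,0), B=(1,0), D=(1/2, sqrt(3)/2)."""
    f = _check_simplex(fractions)
    x = float(f[1] + f[2] / 2)
    y = float(f[2] * math.sqrt(3) / 2)
    return (x, y)


def classify_table(
    results: Sequence[SubgenomeExpression],
    epsilon: float = 0.05,
) -> list[BalanceCall]:
    """Classify every aggregated (gene, context) row, preserving order."""
    return [
        classify(r.fractions, epsilon=epsilon, gene_name=r.gene_name, context=r.context)
        for r in results
    ]
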