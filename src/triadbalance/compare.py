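"""Cross-condition comparison of subgenome expression balance.

Compares a gene's aggregated subgenome expression between two contexts (e.g.
control vs heat stress, leaf vs spike): the shift vector in fraction space
(which sums to zero), the fold change of the summed triad expression, and the
transition between balance categories. "Changed" means the nearest-centroid
category differs between the two contexts at the given epsilon; the boundary
sets are carried along so near-boundary transitions can be inspected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .aggregate import SubgenomeExpression
from .classify import BalanceCall, classify

__all__ = ["ShiftRecord", "CompareError", "compare", "compare_table", "ComparisonTable"]


class CompareError(ValueError):
    """Invalid comparison input (gene mismatch, zero totals, no overlap)."""


@dataclass(frozen=True)
class ShiftRecord:
    """One gene's balance/expression shift between two contexts."""

    gene_name: str
    context_from: tuple[str, str]
    context_to: tuple[str, str]
    fractions_from: tuple[float, float, float]
    fractions_to: tuple[float, float, float]
    delta: tuple[float, float, float]
    fold_change_total: float
    log2_fold_change: float
    category_from: str
    category_to: str
    boundary_from: tuple[str, ...]
    boundary_to: tuple[str, ...]
    changed: bool


def compare(
    gene_from: SubgenomeExpression,
    gene_to: SubgenomeExpression,
    epsilon: float = 0.05,
) -> ShiftRecord:
    """Shift record between two aggregated results for the same gene."""
    if gene_from.gene_name != gene_to.gene_name:
        raise CompareError(
            f"gene mismatch: {gene_from.gene_name!r} vs {gene_to.gene_name!r}"
        )
    total_from = sum(gene_from.totals)
    total_to = sum(gene_to.totals)
    if total_from <= 0 or total_to <= 0:
        raise CompareError(
            f"{gene_from.gene_name}: zero total expression in one of the contexts"
        )
    call_from: BalanceCall = classify(gene_from.fractions, epsilon=epsilon)
    call_to: BalanceCall = classify(gene_to.fractions, epsilon=epsilon)
    delta = tuple(t - f for f, t in zip(gene_from.fractions, gene_to.fractions))
    fc = total_to / total_from
    return ShiftRecord(
        gene_name=gene_from.gene_name,
        context_from=gene_from.context,
        context_to=gene_to.context,
        fractions_from=gene_from.fractions,
        fractions_to=gene_to.fractions,
        delta=delta,  # type: ignore[arg-type]
        fold_change_total=fc,
        log2_fold_change=math.log2(fc),
        category_from=call_from.category,
        category_to=call_to.category,
        boundary_from=call_from.boundary_set,
        boundary_to=call_to.boundary_set,
        changed=call_from.category != call_to.category,
    )


@dataclass(frozen=True)
class ComparisonTable:
    """Per-gene shift records plus the changed/unchanged partition."""

    records: list[ShiftRecord]
    changed: list[str]
    unchanged: list[str]
    missing_from: list[str]  # genes only in the 'to' results
    missing_to: list[str]  # genes only in the 'from' results


def compare_table(
    from_results: Sequence[SubgenomeExpression],
    to_results: Sequence[SubgenomeExpression],
    epsilon: float = 0.05,
) -> ComparisonTable:
    """Compare every gene present in both result sets.

    Genes present on only one side are reported in ``missing_from`` /
    ``missing_to``, never silently dropped. An empty overlap is an error.
    """
    from_by_gene = {r.gene_name: r for r in from_results}
    to_by_gene = {r.gene_name: r for r in to_results}
    shared = [g for g in from_by_gene if g in to_by_gene]
    if not shared:
        raise CompareError("no gene is present in both result sets")
    records = [compare(from_by_gene[g], to_by_gene[g], epsilon=epsilon) for g in shared]
    return ComparisonTable(
        records=records,
        changed=[r.gene_name for r in records if r.changed],
        unchanged=[r.gene_name for r in records if not r.changed],
        missing_from=[g for g in to_by_gene if g not in from_by_gene],
        missing_to=[g for g in from_by_gene if g not in to_by_gene],
    )
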