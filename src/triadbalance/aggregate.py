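"""Subgenome aggregation of TPM expression over homoeolog triads.

Given per-locus TPM values over samples and a triad registry, the analysis
proceeds per gene and per context (a tissue/condition slice of the samples):

1. mean TPM per locus over the selected samples,
2. total TPM per subgenome = sum of its loci's means,
3. relative subgenome expression = each total divided by the grand total
   (a point on the 2-simplex), and
4. log2 of the grand total, used downstream to size plot symbols.

Fractions are undefined for a zero grand total; such (gene, context) pairs
are reported separately rather than silently dropped or pseudocounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import SUBGENOMES, TriadRegistry

__all__ = [
    "ExpressionMatrix",
    "Context",
    "SubgenomeExpression",
    "AggregationError",
    "mean_tpm_per_locus",
    "subgenome_totals",
    "relative_fractions",
    "log2_total",
    "analyze_gene_set",
]


class AggregationError(ValueError):
    """Invalid expression input or an undefined aggregate."""


SampleFilter = Callable[[pd.Series], bool] | Mapping[str, object] | None


@dataclass
class ExpressionMatrix:
    """Long-format locus × sample TPM records with per-sample metadata.

    ``values`` has columns ``locus_id, sample_id, tpm``; ``samples`` is
    indexed by sample_id with columns ``study, tissue, condition``. By default
    every locus must be observed in every sample used — a missing cell is an
    error, because silent zero-fill hides registry/expression mismatches. Set
    ``fill_missing=True`` for inputs that omit zero cells.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    fill_missing: bool = False

    def __post_init__(self) -> None:
        v = self.values
        need = {"locus_id", "sample_id", "tpm"}
        if not need.issubset(v.columns):
            raise AggregationError(f"expression records need columns {sorted(need)}")
        if (v["tpm"] < 0).any():
            bad = v.loc[v["tpm"] < 0].iloc[0]
            raise AggregationError(
                f"negative tpm for locus {bad['locus_id']} in sample {bad['sample_id']}"
            )
        if v.duplicated(["locus_id", "sample_id"]).any():
            dup = v[v.duplicated(["locus_id", "sample_id"])].iloc[0]
            raise AggregationError(
                f"duplicate (locus, sample) record: ({dup['locus_id']}, {dup['sample_id']})"
            )
        meta_need = {"study", "tissue", "condition"}
        if not meta_need.issubset(self.samples.columns):
            raise AggregationError(f"sample metadata needs columns {sorted(meta_need)}")
        known = set(self.samples.index)
        orphans = sorted(set(v["sample_id"]) - known)
        if orphans:
            raise AggregationError(f"samples without metadata: {orphans}")

    @property
    def loci(self) -> list[str]:
        return sorted(set(self.values["locus_id"]))

    def select_samples(self, where: SampleFilter = None) -> list[str]:
        """Sample ids whose metadata row satisfies ``where``.

        ``where`` may be None (all samples), a mapping of metadata column →
        required value (or collection of values), or a callable on the
        metadata row.
        """
        if where is None:
            return list(self.samples.index)
        if callable(where):
            return [sid for sid, row in self.samples.iterrows() if where(row)]
        mask = pd.Series(True, index=self.samples.index)
        for col, val in where.items():
            if col not in self.samples.columns:
                raise AggregationError(f"unknown metadata column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= self.samples[col].isin(list(val))
            else:
                mask &= self.samples[col] == val
        return list(self.samples.index[mask])


@dataclass(frozen=True)
class Context:
    """A labelled sample slice, e.g. tissue='leaf', condition='control'.

    When ``where`` is omitted the tissue/condition labels themselves are
    matched against the sample metadata.
    """

    tissue: str
    condition: str
    where: SampleFilter = None

    @property
    def label(self) -> tuple[str, str]:
        return (self.tissue, self.condition)

    def filter(self) -> SampleFilter:
        return self.where if self.where is not None else {
            "tissue": self.tissue,
            "condition": self.condition,
        }


@dataclass(frozen=True)
class SubgenomeExpression:
    """Per-gene, per-context subgenome totals, fractions and log2 total."""

    gene_name: str
    tissue: str
    condition: str
    total_a: float
    total_b: float
    total_d: float
    frac_a: float
    frac_b: float
    frac_d: float
    log2_total: float
    n_samples: int

    @property
    def context(self) -> tuple[str, str]:
        return (self.tissue, self.condition)

    @property
    def totals(self) -> tuple[float, float, float]:
        return (self.total_a, self.total_b, self.total_d)

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.frac_a, self.frac_b, self.frac_d)


def mean_tpm_per_locus(
    matrix: ExpressionMatrix,
    where: SampleFilter = None,
    stratify_by_study: bool = False,
) -> dict[str, float]:
    """Arithmetic mean TPM per locus over the samples passing ``where``.

    By default all passing samples are pooled with equal weight regardless of
    study; with ``stratify_by_study=True`` a per-study mean is taken first and
    those means are averaged, giving each study equal weight instead.
    """
    sample_ids = matrix.select_samples(where)
    if not sample_ids:
        raise AggregationError("sample filter matched no samples")
    sub = matrix.values[matrix.values["sample_id"].isin(sample_ids)]
    wide = sub.pivot(index="locus_id", columns="sample_id", values="tpm")
    wide = wide.reindex(index=matrix.loci, columns=sample_ids)
    if wide.isna().any().any():
        if not matrix.fill_missing:
            missing = [
                f"({loc}, {smp})"
                for loc, row in wide.iterrows()
                for smp, v in row.items()
                if pd.isna(v)
            ]
            raise AggregationError(
                "missing (locus, sample) cells (set fill_missing=True to zero-fill): "
                + ", ".join(missing[:10])
                + ("..." if len(missing) > 10 else "")
            )
        wide = wide.fillna(0.0)
    if stratify_by_study:
        study = matrix.samples.loc[sample_ids, "study"]
        per_study = wide.T.groupby(study.values).mean()
        means = per_study.mean(axis=0)
    else:
        means = wide.mean(axis=1)
    return {loc: float(m) for loc, m in means.items()}


def subgenome_totals(
    mean_tpm: Mapping[str, float],
    registry: TriadRegistry,
    gene_name: str,
) -> tuple[float, float, float]:
    """Total TPM per subgenome for ``gene_name``: sum of its loci's means.

    E.g. a gene with two A-subgenome loci has total A expression equal to the
    sum of the two loci's mean TPM. Uses the registry's effective subgenome,
    so override-assigned loci contribute to their assigned subgenome.
    """
    loci = {s: registry.loci_for(gene_name, s) for s in SUBGENOMES}
    missing = [l.raw_id for ls in loci.values() for l in ls if l.raw_id not in mean_tpm]
    if missing:
        raise AggregationError(
            f"gene {gene_name!r}: loci absent from the expression data: {missing}"
        )
    ta, tb, td = (
        float(sum(mean_tpm[l.raw_id] for l in loci[s])) for s in SUBGENOMES
    )
    return (ta, tb, td)


def relative_fractions(totals: Sequence[float]) -> tuple[float, float, float]:
    """Relative subgenome expression: each total as a fraction of the sum."""
    ta, tb, td = (float(t) for t in totals)
    if min(ta, tb, td) < 0:
        raise AggregationError("totals must be non-negative")
    s = ta + tb + td
    if s == 0:
        raise AggregationError("fractions are undefined for a zero total")
    return (ta / s, tb / s, td / s)


def log2_total(totals: Sequence[float]) -> float:
    """log2 of the summed subgenome totals. No pseudocount: zero is an error."""
    s = float(sum(totals))
    if s <= 0:
        raise AggregationError("log2 total is undefined for a zero total")
    return math.log2(s)


def analyze_gene_set(
    matrix: ExpressionMatrix,
    registry: TriadRegistry,
    contexts: Sequence[Context],
    genes: Sequence[str] | None = None,
    stratify_by_study: bool = False,
) -> tuple[list[SubgenomeExpression], list[tuple[str, tuple[str, str]]]]:
    """Run the aggregation for every (gene, context) pair.

    Returns ``(results, dropped)`` where ``dropped`` lists (gene, context)
    pairs whose grand total was zero (their fractions are undefined).
    """
    gene_names = list(genes) if genes is not None else registry.gene_names()
    results: list[SubgenomeExpression] = []
    dropped: list[tuple[str, tuple[str, str]]] = []
    for ctx in contexts:
        sample_ids = matrix.select_samples(ctx.filter())
        means = mean_tpm_per_locus(matrix, ctx.filter(), stratify_by_study=stratify_by_study)
        for gene in gene_names:
            totals = subgenome_totals(means, registry, gene)
            if sum(totals) == 0:
                dropped.append((gene, ctx.label))
                continue
            fa, fb, fd = relative_fractions(totals)
            results.append(
                SubgenomeExpression(
                    gene_name=gene,
                    tissue=ctx.tissue,
                    condition=ctx.condition,
                    total_a=totals[0],
                    total_b=totals[1],
                    total_d=totals[2],
                    frac_a=fa,
                    frac_b=fb,
                    frac_d=fd,
                    log2_total=log2_total(totals),
                    n_samples=len(sample_ids),
                )
            )
    return results, dropped
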