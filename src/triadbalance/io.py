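"""Tabular readers/writers for expression data and analysis results.

Formats follow the wheat-expression-browser style: a long TSV of
``gene_id<TAB>sample_id<TAB>tpm`` plus a sample-metadata TSV
``sample_id<TAB>study<TAB>tissue<TAB>condition``; a wide CSV (loci × samples)
is also accepted. Result tables are TSV with floats at 6 decimal places.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .aggregate import ExpressionMatrix, SubgenomeExpression
from .classify import CATEGORY_ORDER, BalanceCall
from .compare import ShiftRecord

__all__ = [
    "read_expression_long",
    "read_expression_wide",
    "read_sample_meta",
    "load_expression",
    "write_subgenome_table",
    "read_subgenome_table",
    "write_calls_table",
    "write_shifts_table",
]

_FLOAT_FMT = "%.6f"


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "study", "tissue", "condition"}
    if not need.issubset(meta.columns):
        raise ValueError(f"sample metadata must have columns {sorted(need)}")
    return meta.set_index("sample_id")


def read_expression_long(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    rename = {"gene_id": "locus_id"}
    df = df.rename(columns=rename)
    need = {"locus_id", "sample_id", "tpm"}
    if not need.issubset(df.columns):
        raise ValueError(
            "long expression table must have columns gene_id/locus_id, sample_id, tpm"
        )
    df["tpm"] = df["tpm"].astype(float)
    return df[["locus_id", "sample_id", "tpm"]]


def read_expression_wide(path) -> pd.DataFrame:
    """Wide CSV with loci as the first column and one column per sample."""
    wide = pd.read_csv(path, index_col=0)
    long = wide.stack().reset_index()
    long.columns = ["locus_id", "sample_id", "tpm"]
    long["tpm"] = long["tpm"].astype(float)
    return long


def load_expression(expression_path, meta_path, wide: bool = False, fill_missing: bool = False) -> ExpressionMatrix:
    values = read_expression_wide(expression_path) if wide else read_expression_long(expression_path)
    samples = read_sample_meta(meta_path)
    return ExpressionMatrix(values=values, samples=samples, fill_missing=fill_missing)


def subgenome_table(results: Sequence[SubgenomeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_name": r.gene_name,
                "tissue": r.tissue,
                "condition": r.condition,
                "total_A": r.total_a,
                "total_B": r.total_b,
                "total_D": r.total_d,
                "frac_A": r.frac_a,
                "frac_B": r.frac_b,
                "frac_D": r.frac_d,
                "log2_total": r.log2_total,
                "n_samples": r.n_samples,
            }
            for r in results
        ]
    )


def write_subgenome_table(results: Sequence[SubgenomeExpression], path) -> None:
    subgenome_table(results).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_subgenome_table(path) -> list[SubgenomeExpression]:
    df = pd.read_csv(path, sep="\t")
    # undo the 6-decimal rounding of the TSV: fractions must sum to 1 exactly
    fsum = df[["frac_A", "frac_B", "frac_D"]].sum(axis=1)
    if ((fsum - 1).abs() > 1e-4).any():
        raise ValueError("frac_A + frac_B + frac_D deviates from 1 beyond rounding error")
    for col in ("frac_A", "frac_B", "frac_D"):
        df[col] = df[col] / fsum
    return [
        SubgenomeExpression(
            gene_name=row.gene_name,
            tissue=str(row.tissue),
            condition=str(row.condition),
            total_a=float(row.total_A),
            total_b=float(row.total_B),
            total_d=float(row.total_D),
            frac_a=float(row.frac_A),
            frac_b=float(row.frac_B),
            frac_d=float(row.frac_D),
            log2_total=float(row.log2_total),
            n_samples=int(row.n_samples),
        )
        for row in df.itertuples(index=False)
    ]


def calls_table(calls: Sequence[BalanceCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "gene_name": c.gene_name,
            "tissue": c.context[0] if c.context else None,
            "condition": c.context[1] if c.context else None,
            "frac_A": c.fractions[0],
            "frac_B": c.fractions[1],
            "frac_D": c.fractions[2],
            "category": c.category,
        }
        for name in CATEGORY_ORDER:
            row[f"dist_{name}"] = c.distances[name]
        row["boundary_set"] = ",".join(c.boundary_set)
        row["ternary_x"], row["ternary_y"] = c.ternary_xy
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls_table(calls: Sequence[BalanceCall], path) -> None:
    calls_table(calls).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def shifts_table(records: Sequence[ShiftRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_name": r.gene_name,
                "tissue_from": r.context_from[0],
                "condition_from": r.context_from[1],
                "tissue_to": r.context_to[0],
                "condition_to": r.context_to[1],
                "frac_A_from": r.fractions_from[0],
                "frac_B_from": r.fractions_from[1],
                "frac_D_from": r.fractions_from[2],
                "frac_A_to": r.fractions_to[0],
                "frac_B_to": r.fractions_to[1],
                "frac_D_to": r.fractions_to[2],
                "delta_A": r.delta[0],
                "delta_B": r.delta[1],
                "delta_D": r.delta[2],
                "fold_change_total": r.fold_change_total,
                "log2_fold_change": r.log2_fold_change,
                "category_from": r.category_from,
                "category_to": r.category_to,
                "changed": r.changed,
            }
            for r in records
        ]
    )


def write_shifts_table(records: Sequence[ShiftRecord], path) -> None:
    shifts_table(records).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
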