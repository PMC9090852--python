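"""Synthetic triad expression and homoeolog sequence data with known truth.

The generator emulates the data shape the analysis assumes: homoeolog triads
(optionally multi-copy per subgenome, like the tandem RbcS family), TPM values
over replicate samples per context, multiplicative log-normal per-sample noise,
a stress context that up-regulates specific homoeologs, and near-identical
homoeolog sequences differing at a controlled number of positions. Everything
is reproducible from a single seed.

Noise model: tpm = expected × N where N is log-normal with mean 1 and a given
coefficient of variation (sigma² = ln(1 + cv²), mu = −sigma²/2). Within a
subgenome, gene copies split the subgenome's expected share equally — the
downstream aggregation sums copies, so only the subgenome total matters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import ExpressionMatrix
from .classify import classify
from .registry import SUBGENOMES

__all__ = [
    "GeneSpec",
    "StressEffect",
    "SimulationSpec",
    "TruthTable",
    "simulate_dataset",
    "simulate_homoeolog_sequences",
]


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: copy numbers, true balance, and expression level."""

    name: str
    loci_per_subgenome: tuple[int, int, int] = (1, 1, 1)
    true_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    base_total_tpm: float = 100.0


@dataclass(frozen=True)
class StressEffect:
    """Multiplier applied to one gene's subgenome in the stress context."""

    gene_name: str
    subgenome: str
    multiplier: float


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a simulated dataset.

    ``contexts`` are (tissue, condition) labels; ``n_samples`` replicates are
    drawn per context. ``stress_effects`` apply only in ``stress_context``.
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal per-(locus, sample) noise; 0 gives deterministic output.
    """

    genes: tuple[GeneSpec, ...]
    n_samples: int = 10
    contexts: tuple[tuple[str, str], ...] = (("leaf", "control"),)
    stress_context: tuple[str, str] | None = None
    stress_effects: tuple[StressEffect, ...] = ()
    noise_cv: float = 0.0
    seed: int = 0
    study: str = "sim_study"

    def validate(self) -> None:
        if not self.genes:
            raise ValueError("spec must define at least one gene")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in spec")
        for g in self.genes:
            if any(n < 1 for n in g.loci_per_subgenome):
                raise ValueError(f"{g.name}: loci_per_subgenome must be positive")
            if abs(sum(g.true_fractions) - 1.0) > 1e-9 or min(g.true_fractions) < 0:
                raise ValueError(f"{g.name}: true_fractions must be a simplex triple")
            if g.base_total_tpm <= 0:
                raise ValueError(f"{g.name}: base_total_tpm must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        for eff in self.stress_effects:
            if eff.subgenome not in SUBGENOMES:
                raise ValueError(f"stress effect subgenome must be one of {SUBGENOMES}")
            if eff.multiplier <= 0:
                raise ValueError("stress multipliers must be positive")
            if eff.gene_name not in names:
                raise ValueError(f"stress effect for unknown gene {eff.gene_name!r}")
        if self.stress_effects and self.stress_context is None:
            raise ValueError("stress_effects given but no stress_context")
        if self.stress_context is not None and self.stress_context not in self.contexts:
            raise ValueError("stress_context must be one of the contexts")


@dataclass
class TruthTable:
    """Ground truth implied by a SimulationSpec (noise-free expectations)."""

    fractions: dict[tuple[str, tuple[str, str]], tuple[float, float, float]] = field(
        default_factory=dict
    )
    totals: dict[tuple[str, tuple[str, str]], float] = field(default_factory=dict)
    categories: dict[tuple[str, tuple[str, str]], str] = field(default_factory=dict)
    changed: dict[tuple[str, tuple[str, str], tuple[str, str]], bool] = field(
        default_factory=dict
    )


def _expected_totals(
    gene: GeneSpec, stressed: bool, effects: Mapping[tuple[str, str], float]
) -> tuple[float, float, float]:
    out = []
    for sg, frac in zip(SUBGENOMES, gene.true_fractions):
        mult = effects.get((gene.name, sg), 1.0) if stressed else 1.0
        out.append(gene.base_total_tpm * frac * mult)
    return tuple(out)  # type: ignore[return-value]


def _synthetic_gene_id(gene_index: int, subgenome: str, counter: int) -> str:
    chromosome = (gene_index % 7) + 1
    return f"TraesCS{chromosome}{subgenome}02G{counter * 100:06d}"


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, ExpressionMatrix, TruthTable]:
    """Generate (registry table, expression matrix, truth table) from a spec.

    The registry table has columns ``gene_name, gene_id`` with well-formed
    synthetic wheat identifiers, loadable by :func:`triadbalance.load_registry`.
    Per-locus per-sample TPM is
    ``base_total × fraction / copies × stress multiplier × noise``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    effects = {(e.gene_name, e.subgenome): e.multiplier for e in spec.stress_effects}

    # Registry
    reg_rows = []
    locus_ids: dict[tuple[str, str], list[str]] = {}
    counter = itertools.count(1)
    for gi, gene in enumerate(spec.genes):
        for sg, n_copies in zip(SUBGENOMES, gene.loci_per_subgenome):
            ids = [_synthetic_gene_id(gi, sg, next(counter)) for _ in range(n_copies)]
            locus_ids[(gene.name, sg)] = ids
            reg_rows += [{"gene_name": gene.name, "gene_id": i} for i in ids]
    registry_df = pd.DataFrame(reg_rows, columns=["gene_name", "gene_id"])

    # Noise parameters: log-normal with mean 1, CV = noise_cv.
    if spec.noise_cv > 0:
        sigma2 = float(np.log1p(spec.noise_cv**2))
        sigma = float(np.sqrt(sigma2))
        mu = -sigma2 / 2
    else:
        sigma = mu = 0.0

    records = []
    meta_rows = []
    for ctx in spec.contexts:
        tissue, condition = ctx
        stressed = ctx == spec.stress_context
        sample_ids = [f"{tissue}_{condition}_s{i:02d}" for i in range(1, spec.n_samples + 1)]
        for sid in sample_ids:
            meta_rows.append(
                {"sample_id": sid, "study": spec.study, "tissue": tissue, "condition": condition}
            )
        for gene in spec.genes:
            exp_totals = _expected_totals(gene, stressed, effects)
            for sg, n_copies, sg_total in zip(SUBGENOMES, gene.loci_per_subgenome, exp_totals):
                per_copy = sg_total / n_copies
                for locus in locus_ids[(gene.name, sg)]:
                    if spec.noise_cv > 0:
                        noise = rng.lognormal(mean=mu, sigma=sigma, size=spec.n_samples)
                    else:
                        noise = np.ones(spec.n_samples)
                    for sid, nz in zip(sample_ids, noise):
                        records.append(
                            {"locus_id": locus, "sample_id": sid, "tpm": per_copy * float(nz)}
                        )

    values = pd.DataFrame(records, columns=["locus_id", "sample_id", "tpm"])
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    matrix = ExpressionMatrix(values=values, samples=samples)

    truth = TruthTable()
    for gene in spec.genes:
        for ctx in spec.contexts:
            stressed = ctx == spec.stress_context
            totals = _expected_totals(gene, stressed, effects)
            s = sum(totals)
            fracs = tuple(t / s for t in totals)
            truth.totals[(gene.name, ctx)] = s
            truth.fractions[(gene.name, ctx)] = fracs  # type: ignore[assignment]
            truth.categories[(gene.name, ctx)] = classify(fracs).category
        for c1 in spec.contexts:
            for c2 in spec.contexts:
                if c1 == c2:
                    continue
                truth.changed[(gene.name, c1, c2)] = (
                    truth.categories[(gene.name, c1)] != truth.categories[(gene.name, c2)]
                )
    return registry_df, matrix, truth


_DNA = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_homoeolog_sequences(
    base_length: int,
    substitutions: Mapping[tuple[str, str], int],
    alphabet: str = "protein",
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str, str]]]:
    """Three homoeolog sequences (A, B, D) with exact pairwise differences.

    ``substitutions`` maps subgenome pairs, e.g. ``{("A","B"): 4}``, to the
    number of substituted positions between those two sequences (unspecified
    pairs default to 0). Internally each homoeolog receives private
    substitutions relative to a common ancestral sequence at distinct
    positions, so the requested pairwise counts must satisfy
    ``n_XY = n_X + n_Y`` for non-negative integers per sequence; infeasible
    combinations raise ValueError.

    Returns ``(records, truth)`` where records are (subgenome, sequence) pairs
    and truth lists (subgenome, 1-based position, ancestral residue, new
    residue) for every substitution introduced.
    """
    if base_length < 1:
        raise ValueError("base_length must be positive")
    norm: dict[frozenset[str], int] = {}
    for pair, count in substitutions.items():
        key = frozenset(pair)
        if not key.issubset(set(SUBGENOMES)) or len(key) != 2:
            raise ValueError(f"invalid subgenome pair {pair!r}")
        if count < 0:
            raise ValueError("substitution counts must be non-negative")
        norm[key] = norm.get(key, 0) + count
    n_ab = norm.get(frozenset(("A", "B")), 0)
    n_ad = norm.get(frozenset(("A", "D")), 0)
    n_bd = norm.get(frozenset(("B", "D")), 0)
    twice_a = n_ab + n_ad - n_bd
    twice_b = n_ab + n_bd - n_ad
    twice_d = n_ad + n_bd - n_ab
    if any(x < 0 or x % 2 for x in (twice_a, twice_b, twice_d)):
        raise ValueError(
            f"pairwise substitution counts (A-B={n_ab}, A-D={n_ad}, B-D={n_bd}) are not "
            "realizable as private per-sequence substitutions at distinct positions"
        )
    private = {"A": twice_a // 2, "B": twice_b // 2, "D": twice_d // 2}
    n_total = sum(private.values())
    if n_total > base_length:
        raise ValueError(
            f"{n_total} substituted positions exceed sequence length {base_length}"
        )

    letters = _AA if alphabet == "protein" else _DNA
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list(letters), size=base_length))
    positions = rng.choice(base_length, size=n_total, replace=False)
    seqs = {sg: list(base) for sg in SUBGENOMES}
    truth: list[tuple[str, int, str, str]] = []
    pos_iter = iter(positions)
    for sg in SUBGENOMES:
        for _ in range(private[sg]):
            p = int(next(pos_iter))
            old = base[p]
            new = rng.choice([c for c in letters if c != old])
            seqs[sg][p] = str(new)
            truth.append((sg, p + 1, old, str(new)))
    records = [(sg, "".join(seqs[sg])) for sg in SUBGENOMES]
    truth.sort(key=lambda t: (t[0], t[1]))
    return records, truth
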