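"""Independent brute-force oracles used to check the library's numerics.

These deliberately avoid the library's own code paths: alignment optima come
from exhaustive enumeration of all global alignments (and from a separate
three-state recursion), simplex distances from direct arithmetic, and
aggregation totals from a plain double loop over expression records.
"""

from __future__ import annotations

import functools
import math

GAP = "-"


def score_alignment(aligned_a: str, aligned_b: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Affine score of a finished alignment; a gap run of length L costs
    open + (L-1)*extend, counted separately per row."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP:
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b)."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, GAP + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield (GAP + ra, b[0] + rb)
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def best_score_enumeration(a: str, b: str, match: float, mismatch: float,
                           gap_open: float, gap_extend: float) -> float:
    return max(
        score_alignment(ra, rb, match, mismatch, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def best_score_gotoh(a: str, b: str, match: float, mismatch: float,
                     gap_open: float, gap_extend: float) -> float:
    """Three-state affine recursion (match / gap-in-a / gap-in-b) with memo."""
    NEG = float("-inf")

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = last column was a residue pair, 1 = gap in a, 2 = gap in b
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + rec(i + 1, j + 1, 0))
        if j < len(b):  # gap in a, consumes b[j]
            cost = gap_extend if state == 1 else gap_open
            best = max(best, cost + rec(i, j + 1, 1))
        if i < len(a):  # gap in b, consumes a[i]
            cost = gap_extend if state == 2 else gap_open
            best = max(best, cost + rec(i + 1, j, 2))
        return best

    return rec(0, 0, 0)


def simplex_distances(fractions, centroids) -> dict[str, float]:
    """Euclidean distance in raw 3-space to each centroid, by direct arithmetic."""
    fa, fb, fd = fractions
    out = {}
    for name, (ca, cb, cd) in centroids.items():
        out[name] = math.sqrt((fa - ca) ** 2 + (fb - cb) ** 2 + (fd - cd) ** 2)
    return out


def brute_force_totals(records, locus_to_subgenome, sample_ids):
    """Per-subgenome totals of per-locus mean tpm via a plain double loop.

    ``records`` is an iterable of (locus_id, sample_id, tpm).
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for locus, sample, tpm in records:
        if sample in sample_ids:
            sums[locus] = sums.get(locus, 0.0) + tpm
            counts[locus] = counts.get(locus, 0) + 1
    totals = {"A": 0.0, "B": 0.0, "D": 0.0}
    for locus, sg in locus_to_subgenome.items():
        if locus in sums:
            totals[sg] += sums[locus] / counts[locus]
    return (totals["A"], totals["B"], totals["D"])
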