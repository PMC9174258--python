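"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by direct enumeration or a naive scan,
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_upper_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided Fisher p by exact rational enumeration of all tables with
    the observed margins and a' >= a."""
    n_total = a + b + c + d
    K = a + c   # mutated samples
    n = a + b   # case samples
    denom = comb(n_total, n)
    total = Fraction(0)
    for a2 in range(max(0, n + K - n_total), min(n, K) + 1):
        if a2 < a:
            continue
        total += Fraction(comb(K, a2) * comb(n_total - K, n - a2), denom)
    return total


def binom_upper_tail_exact(y: int, s: int, p_num: int, p_den: int) -> Fraction:
    """P(X >= y) for X ~ Binomial(s, p_num/p_den) by exact summation."""
    p = Fraction(p_num, p_den)
    total = Fraction(0)
    for k in range(y, s + 1):
        total += comb(s, k) * p**k * (1 - p) ** (s - k)
    return total


def naive_overlap_bp(gene_start: int, gene_end: int, intervals) -> int:
    """bp of [gene_start, gene_end) covered by the union of intervals,
    counted base by base (correct for desk-scale inputs by construction)."""
    covered = set()
    for s, e in intervals:
        lo, hi = max(s, gene_start), min(e, gene_end)
        covered.update(range(lo, hi))
    return len(covered)


def naive_overlapping(gene, intervals):
    """All-pairs scan: intervals sharing >= 1 bp with the gene."""
    return [
        iv for iv in intervals
        if iv.chrom == gene.chrom and iv.start < gene.end and iv.end > gene.start
    ]
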