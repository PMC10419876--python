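"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (character loops, full sorts,
direct summation) and shares no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def _context_of(tri: str) -> str:
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def brute_force_sites(chrom: str, seq: str) -> list[tuple]:
    """Character-by-character cytosine context enumeration on both strands."""
    seq = seq.upper()
    n = len(seq)
    rows = []
    for i, base in enumerate(seq):
        if base == "C" and i + 2 < n:
            tri = seq[i : i + 3]
            if "N" not in tri:
                rows.append((chrom, i, "+", _context_of(tri), tri))
        if base == "G" and i >= 2:
            tri = revcomp_oracle(seq[i - 2 : i + 1])
            if "N" not in tri:
                rows.append((chrom, i, "-", _context_of(tri), tri))
    rows.sort()
    return rows


def binom_upper_tail(m: int, n: int, r: float) -> float:
    """P(X >= m), X ~ Binomial(n, r), by direct summation."""
    return sum(
        math.comb(n, k) * r**k * (1.0 - r) ** (n - k) for k in range(m, n + 1)
    )


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by explicit sort + running min."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [0.0] * n
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * n / rank_from_top)
        adjusted[i] = running
    return adjusted


def average_ranks(values: list[float]) -> list[float]:
    """Ranks with ties replaced by the average rank."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x: list[float], y: list[float]) -> float:
    """Spearman rho: Pearson correlation of average ranks."""
    rx = np.array(average_ranks(list(x)))
    ry = np.array(average_ranks(list(y)))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
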