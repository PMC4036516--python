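"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: plain Python
loops over every window/strand/motif, quadratic pair enumeration, exhaustive
multiset-permutation nulls, and exact rational hypergeometric tails.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def hamming(a: str, b: str) -> int:
    # N mismatches everything, including another N
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def brute_occurrences(seq, motifs, max_mismatch):
    """Every (start, strand, motif_name, mismatches) with mm <= max_mismatch."""
    out = []
    for i in range(len(seq) - 5):
        window = seq[i : i + 6]
        for name, pattern in motifs:
            for strand, target in (("+", pattern), ("-", revcomp(pattern))):
                mm = hamming(window, target)
                if mm <= max_mismatch:
                    out.append((i, strand, name, mm))
    out.sort()
    return out


def brute_pairs(occurrences, window=20, require_nonoverlap=True,
                distance_mode="gap"):
    """Quadratic pair enumeration; returns (total, per-class counts)."""
    per_class: dict[tuple[str, str], int] = {}
    total = 0
    for a, b in itertools.combinations(sorted(occurrences), 2):
        first, second = (a, b) if a[0] <= b[0] else (b, a)
        gap = second[0] - (first[0] + 6)
        if require_nonoverlap and gap < 0:
            continue
        dist = gap if distance_mode == "gap" else second[0] - first[0]
        if dist > window:
            continue
        pc = tuple(sorted((first[2], second[2])))
        per_class[pc] = per_class.get(pc, 0) + 1
        total += 1
    return total, per_class


def brute_total_pairs(seq, motifs, max_mismatch=1, window=20):
    occs = brute_occurrences(seq, motifs, max_mismatch)
    return brute_pairs(occs, window)[0]


def exact_fraction_fewer(seq, motifs, max_mismatch=1, window=20):
    """Exact P(shuffle has strictly fewer pairs than seq) by enumeration.

    A uniform permutation of the characters is uniform over the distinct
    multiset arrangements, so enumerating each distinct arrangement once
    gives the exact fraction.
    """
    from sympy.utilities.iterables import multiset_permutations

    actual = brute_total_pairs(seq, motifs, max_mismatch, window)
    fewer = 0
    total = 0
    for arrangement in multiset_permutations(list(seq)):
        total += 1
        if brute_total_pairs("".join(arrangement), motifs, max_mismatch, window) < actual:
            fewer += 1
    return Fraction(fewer, total), actual


def hypergeom_tail_enum(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) by enumerating all C(N, n) draws (tiny N only)."""
    universe = list(range(N))
    marked = set(range(K))
    hits = sum(
        1
        for draw in itertools.combinations(universe, n)
        if sum(1 for g in draw if g in marked) >= k
    )
    return Fraction(hits, comb(N, n))


def bh_hand(pvals):
    """Step-up BH computed longhand: m*p_(i)/i with cumulative min from the top."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = min(running, 1.0)
    return adj


def brute_read_targets(blocks_by_chrom, genes, min_overlap=1):
    """Genes whose exon spans intersect any aligned block by >= min_overlap."""
    targets = set()
    for g in genes:
        for chrom, blocks in blocks_by_chrom:
            if chrom != g.chrom:
                continue
            for bs, be in blocks:
                for xs, xe in g.exon_spans:
                    if min(be, xe) - max(bs, xs) + 1 >= min_overlap:
                        targets.add(g.gene_id)
    return targets
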