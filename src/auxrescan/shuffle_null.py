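"""Per-promoter sequence-shuffle permutation null for AuxRE pair counts.

Each promoter is compared against its own composition-matched null: the
sequence is shuffled ``n_shuffles`` times (a uniform permutation of its
characters, preserving the exact base multiset), pairs are recounted on
every shuffle, and the summary reports the null mean, the null standard
deviation (population SD over the shuffle values) and ``fraction_fewer``,
the fraction of shuffles with *strictly* fewer total pairs than the real
sequence.  A promoter is called significant when ``fraction_fewer`` is at
least the significance fraction (0.95 by default); ties count against
significance, so a promoter with zero real pairs can never be significant.

Each promoter gets its own RNG stream derived from the master seed and a
stable hash of the promoter id, so results do not depend on processing
order.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .pairscan import (
    MOTIF_LEN,
    CompiledMotifs,
    ScanConfig,
    count_pairs,
    encode_sequence,
    find_occurrences,
    mismatch_matrix,
    total_pairs_from_starts,
)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class NullConfig:
    n_shuffles: int = 100
    significance_fraction: float = 0.95
    seed: int = 0
    dinucleotide: bool = False

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not (0 < self.significance_fraction <= 1):
            raise ValueError("significance_fraction must be in (0, 1]")


@dataclass(frozen=True)
class NullStats:
    promoter_id: str
    actual_pairs: int
    null_mean: float
    null_sd: float
    fraction_fewer: float
    significant: bool
    promoter_length: int = 0
    pair_counts: Optional[dict] = None


def promoter_rng(seed: int, promoter_id: str) -> np.random.Generator:
    """Per-promoter RNG stream from (master seed, stable id hash)."""
    h = int.from_bytes(
        hashlib.sha256(promoter_id.encode("utf-8")).digest()[:4], "big"
    )
    return np.random.default_rng([seed, h])


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniform random permutation of the sequence's characters."""
    codes = encode_sequence(seq)
    return _DECODE[rng.permutation(codes)].tobytes().decode("ascii")


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving exact dinucleotide counts (Altschul-Erickson).

    Builds the multigraph whose edges are the sequence's dinucleotides and
    samples a uniform random Eulerian path with the original first and last
    characters fixed, via the random-arborescence ("last-edge") method.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges.keys() | set(seq))
    while True:
        # pick a random last outgoing edge for each vertex except `last`
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last or not edges.get(v):
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # the chosen last edges must form paths leading to `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        # shuffle remaining edges, append the reserved last edge
        pools: dict[str, list[str]] = {}
        for v, targets in edges.items():
            t = list(targets)
            if v in last_edge:
                t.remove(last_edge[v])
            rng.shuffle(t)
            if v in last_edge:
                t.append(last_edge[v])
            pools[v] = t
        out = [first]
        cur = first
        for _ in range(len(seq) - 1):
            nxt = pools[cur].pop(0)
            out.append(nxt)
            cur = nxt
        return "".join(out)


def _null_totals_fast(
    codes: np.ndarray,
    compiled: CompiledMotifs,
    scan_config: ScanConfig,
    n_shuffles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Total pair counts over n_shuffles mononucleotide shuffles, vectorised.

    Only valid for the default pairing rule (gap distance, non-overlap)."""
    mat = np.tile(codes, (n_shuffles, 1))
    mat = rng.permuted(mat, axis=1)
    mm = mismatch_matrix(mat, compiled)  # (n_shuffles, combos, windows)
    hits = mm <= scan_config.max_mismatch
    totals = np.empty(n_shuffles, dtype=np.int64)
    for r in range(n_shuffles):
        _, win_idx = np.nonzero(hits[r])
        win_idx.sort()
        totals[r] = total_pairs_from_starts(win_idx, scan_config.window)
    return totals


def null_test(
    promoter,
    scan_config: ScanConfig = ScanConfig(),
    null_config: NullConfig = NullConfig(),
) -> NullStats:
    """Shuffle-null significance test for one promoter.

    ``promoter`` is any object with ``gene_id`` and ``sequence`` attributes
    (a string id + sequence pair also works via ``null_test_seq``).
    """
    return null_test_seq(promoter.gene_id, promoter.sequence, scan_config, null_config)


def null_test_seq(
    promoter_id: str,
    seq: str,
    scan_config: ScanConfig = ScanConfig(),
    null_config: NullConfig = NullConfig(),
) -> NullStats:
    rng = promoter_rng(null_config.seed, promoter_id)
    actual = count_pairs(
        find_occurrences(seq, scan_config.motifs, scan_config.max_mismatch,
                         promoter_id),
        scan_config,
    )

    fast = (
        not null_config.dinucleotide
        and scan_config.distance_mode == "gap"
        and scan_config.require_nonoverlap
        and len(seq) >= MOTIF_LEN
    )
    if fast:
        compiled = CompiledMotifs(scan_config.motifs)
        totals = _null_totals_fast(
            encode_sequence(seq), compiled, scan_config, null_config.n_shuffles, rng
        )
    else:
        shuffler = dinucleotide_shuffle if null_config.dinucleotide else shuffle_sequence
        totals = np.empty(null_config.n_shuffles, dtype=np.int64)
        for i in range(null_config.n_shuffles):
            shuf = shuffler(seq, rng)
            occs = find_occurrences(shuf, scan_config.motifs, scan_config.max_mismatch)
            totals[i] = count_pairs(occs, scan_config).total_pairs

    fraction_fewer = float(np.mean(totals < actual.total_pairs))
    return NullStats(
        promoter_id=promoter_id,
        actual_pairs=actual.total_pairs,
        null_mean=float(totals.mean()),
        null_sd=float(totals.std()),  # population SD
        fraction_fewer=fraction_fewer,
        significant=fraction_fewer >= null_config.significance_fraction,
        promoter_length=len(seq),
        pair_counts=dict(actual.pair_counts),
    )


def null_test_cohort(
    promoters: Iterable,
    scan_config: ScanConfig = ScanConfig(),
    null_config: NullConfig = NullConfig(),
) -> list[NullStats]:
    return [null_test(p, scan_config, null_config) for p in promoters]


def summarize_significant(
    stats: Sequence[NullStats],
) -> tuple[int, int, float]:
    """(n_significant, n_tested, fraction); length-0 promoters are not tested.

    With no testable promoters the fraction is NaN.
    """
    tested = [s for s in stats if s.promoter_length > 0]
    n_sig = sum(1 for s in tested if s.significant)
    n_tested = len(tested)
    frac = n_sig / n_tested if n_tested else float("nan")
    return n_sig, n_tested, frac


def stats_to_frame(
    stats: Sequence[NullStats], scan_config: ScanConfig = ScanConfig()
) -> pd.DataFrame:
    classes = scan_config.pair_classes
    rows = []
    for s in stats:
        row = {
            "promoter_id": s.promoter_id,
            "length": s.promoter_length,
            "actual_pairs": s.actual_pairs,
            "null_mean": s.null_mean,
            "null_sd": s.null_sd,
            "fraction_fewer": s.fraction_fewer,
            "significant": s.significant,
        }
        for pc in classes:
            row[f"pairs_{pc[0]}_{pc[1]}"] = (s.pair_counts or {}).get(pc, 0)
        rows.append(row)
    cols = [
        "promoter_id", "length", "actual_pairs", "null_mean", "null_sd",
        "fraction_fewer", "significant",
    ] + [f"pairs_{a}_{b}" for a, b in classes]
    return pd.DataFrame(rows, columns=cols)
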