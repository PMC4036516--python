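"""Mismatch-tolerant AuxRE motif scanning and windowed pair counting.

Auxin response factors bind short AuxRE hexamers (canonically TGTCTC and
the variants TGTCGG and TGTCGA).  This module finds all occurrences of a
hexamer set on both strands of a promoter, allowing up to one mismatch,
and counts unordered pairs of occurrences whose inter-motif gap is within
a pairing window (20 bp by default), broken down by pair class (the
unordered pair of motif names).

The hot loop is vectorised: sequences are encoded as small integer arrays
and mismatch counts per window are computed with shifted comparisons, so
the same code path scales to the tens of thousands of scans a permutation
null requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MOTIF_LEN = 6

# A=0 C=1 G=2 T=3 N=4; N mismatches every pattern base.
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 code array (others become N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) != MOTIF_LEN:
            raise ValueError(f"motif {self.name}: pattern must be {MOTIF_LEN} nt")
        if set(self.pattern) - set("ACGT"):
            raise ValueError(f"motif {self.name}: pattern must be over ACGT")


DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("TGTCGG", "TGTCGG"),
    Motif("TGTCGA", "TGTCGA"),
    Motif("TGTCTC", "TGTCTC"),
)


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the pair scan.

    ``window`` is the maximum inter-motif gap (end of the first occurrence
    to start of the second) in bases; ``distance_mode='start'`` switches to
    a start-to-start distance instead.  With ``require_nonoverlap`` (the
    default) occurrences whose 6-mer extents overlap never form a pair.
    """

    window: int = 20
    max_mismatch: int = 1
    motifs: tuple[Motif, ...] = DEFAULT_MOTIFS
    require_nonoverlap: bool = True
    distance_mode: str = "gap"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")
        if self.distance_mode not in ("gap", "start"):
            raise ValueError("distance_mode must be 'gap' or 'start'")

    @property
    def pair_classes(self) -> list[tuple[str, str]]:
        names = [m.name for m in self.motifs]
        out = []
        for i, a in enumerate(names):
            for b in names[i:]:
                out.append(tuple(sorted((a, b))))
        return out


@dataclass(frozen=True)
class MotifOccurrence:
    """One mismatch-tolerant motif match on a promoter.

    ``start`` is the 0-based offset of the 6-mer window in the promoter
    sequence; ``strand`` is relative to the promoter sequence (``-`` means
    the window matches the reverse complement of the pattern).
    """

    promoter_id: str
    start: int
    strand: str
    motif_name: str
    mismatches: int

    @property
    def end(self) -> int:
        """0-based exclusive end of the matched window."""
        return self.start + MOTIF_LEN


@dataclass(frozen=True)
class PairHit:
    occurrence_a: MotifOccurrence
    occurrence_b: MotifOccurrence
    gap: int

    @property
    def pair_class(self) -> tuple[str, str]:
        return tuple(
            sorted((self.occurrence_a.motif_name, self.occurrence_b.motif_name))
        )


@dataclass
class PromoterScanResult:
    promoter_id: str
    occurrences: list[MotifOccurrence]
    pair_counts: dict[tuple[str, str], int]
    total_pairs: int
    pairs: list[PairHit] = field(default_factory=list)


class CompiledMotifs:
    """Motif patterns pre-encoded for vectorised scanning.

    One row per (motif, strand) combination: the forward pattern and the
    reverse complement of the pattern (a ``-`` strand occurrence is a window
    equal to the pattern's reverse complement).
    """

    def __init__(self, motifs: Sequence[Motif]):
        self.motifs = tuple(motifs)
        pats, names, strands = [], [], []
        for m in motifs:
            fwd = encode_sequence(m.pattern)
            rev = _RC_CODE[fwd][::-1]
            pats.extend([fwd, rev])
            names.extend([m.name, m.name])
            strands.extend(["+", "-"])
        self.patterns = np.stack(pats)  # (n_combos, 6)
        self.names = names
        self.strands = strands


def mismatch_matrix(codes: np.ndarray, compiled: CompiledMotifs) -> np.ndarray:
    """Per-window mismatch counts.

    ``codes`` is a 1-D code array (one sequence) or 2-D (one sequence per
    row, equal lengths).  Returns an int8 array of shape
    (n_rows, n_combos, n_windows); the row axis is dropped for 1-D input.
    """
    squeeze = codes.ndim == 1
    if squeeze:
        codes = codes[None, :]
    n_rows, L = codes.shape
    n_win = L - MOTIF_LEN + 1
    if n_win <= 0:
        out = np.zeros((n_rows, len(compiled.names), 0), dtype=np.int8)
        return out[0] if squeeze else out
    pats = compiled.patterns  # (C, 6)
    mm = np.zeros((n_rows, pats.shape[0], n_win), dtype=np.int8)
    for j in range(MOTIF_LEN):
        # (rows, 1, windows) vs (1, combos, 1)
        mm += codes[:, None, j : j + n_win] != pats[None, :, j, None]
    return mm[0] if squeeze else mm


def find_occurrences(
    seq: str,
    motifs: Sequence[Motif] = DEFAULT_MOTIFS,
    max_mismatch: int = 1,
    promoter_id: str = "",
) -> list[MotifOccurrence]:
    """All motif occurrences on both strands with <= max_mismatch mismatches.

    N in the sequence counts as a mismatch against every pattern base.
    Sequences shorter than 6 nt yield an empty list.  The result is sorted
    by (start, strand, motif name).
    """
    compiled = CompiledMotifs(motifs)
    codes = encode_sequence(seq)
    mm = mismatch_matrix(codes, compiled)
    occs = []
    combo_idx, win_idx = np.nonzero(mm <= max_mismatch)
    for c, w in zip(combo_idx.tolist(), win_idx.tolist()):
        occs.append(
            MotifOccurrence(
                promoter_id=promoter_id,
                start=w,
                strand=compiled.strands[c],
                motif_name=compiled.names[c],
                mismatches=int(mm[c, w]),
            )
        )
    occs.sort(key=lambda o: (o.start, o.strand, o.motif_name))
    return occs


def _pair_admissible(
    a: MotifOccurrence, b: MotifOccurrence, config: ScanConfig
) -> tuple[bool, int]:
    """Whether occurrences a, b (a.start <= b.start) form a pair; returns gap."""
    gap = b.start - a.end
    overlap = b.start < a.end
    if config.require_nonoverlap and overlap:
        return False, gap
    dist = gap if config.distance_mode == "gap" else b.start - a.start
    return dist <= config.window, gap


def count_pairs(
    occurrences: Sequence[MotifOccurrence],
    config: ScanConfig = ScanConfig(),
    keep_pairs: bool = False,
) -> PromoterScanResult:
    """Count unordered occurrence pairs within the pairing window, by class.

    Every admissible unordered pair contributes 1 to its pair class; an
    occurrence may participate in any number of pairs, and pairs may mix
    strands.
    """
    occs = sorted(occurrences, key=lambda o: (o.start, o.strand, o.motif_name))
    promoter_id = occs[0].promoter_id if occs else ""
    pair_counts = {pc: 0 for pc in config.pair_classes}
    pairs: list[PairHit] = []
    total = 0
    for i, a in enumerate(occs):
        for b in occs[i + 1 :]:
            # sorted by start: once b is beyond reach, stop
            if b.start - a.start - MOTIF_LEN > config.window:
                break
            ok, gap = _pair_admissible(a, b, config)
            if not ok:
                continue
            pc = tuple(sorted((a.motif_name, b.motif_name)))
            pair_counts[pc] = pair_counts.get(pc, 0) + 1
            total += 1
            if keep_pairs:
                pairs.append(PairHit(a, b, gap))
    return PromoterScanResult(
        promoter_id=promoter_id,
        occurrences=list(occs),
        pair_counts=pair_counts,
        total_pairs=total,
        pairs=pairs,
    )


def total_pairs_from_starts(starts: np.ndarray, window: int) -> int:
    """Fast total pair count from sorted occurrence starts.

    Valid only for the default pairing rule (gap distance, non-overlapping
    occurrences): partners of an occurrence at s are all occurrences with
    start in [s + 6, s + 6 + window].  Duplicate starts (one window matching
    several motif/strand combinations) are distinct occurrences and must be
    present with multiplicity.
    """
    if starts.size < 2:
        return 0
    lo = np.searchsorted(starts, starts + MOTIF_LEN, side="left")
    hi = np.searchsorted(starts, starts + MOTIF_LEN + window, side="right")
    return int((hi - lo).sum())


def scan_promoter(
    promoter_id: str, seq: str, config: ScanConfig = ScanConfig()
) -> PromoterScanResult:
    occs = find_occurrences(seq, config.motifs, config.max_mismatch, promoter_id)
    res = count_pairs(occs, config)
    res.promoter_id = promoter_id
    return res


def scan_promoters(
    promoters: Iterable, config: ScanConfig = ScanConfig()
) -> list[PromoterScanResult]:
    """Scan a promoter collection (objects with .gene_id and .sequence)."""
    return [scan_promoter(p.gene_id, p.sequence, config) for p in promoters]


def results_to_frame(
    results: Sequence[PromoterScanResult], config: ScanConfig = ScanConfig()
) -> pd.DataFrame:
    """Tabulate scan results: one row per promoter, one column per pair class."""
    classes = config.pair_classes
    rows = []
    for r in results:
        row = {
            "promoter_id": r.promoter_id,
            "n_occurrences": len(r.occurrences),
        }
        for pc in classes:
            row[f"pairs_{pc[0]}_{pc[1]}"] = r.pair_counts.get(pc, 0)
        row["total_pairs"] = r.total_pairs
        rows.append(row)
    cols = (
        ["promoter_id", "n_occurrences"]
        + [f"pairs_{a}_{b}" for a, b in classes]
        + ["total_pairs"]
    )
    return pd.DataFrame(rows, columns=cols)


def read_motifs_tsv(path: str) -> tuple[Motif, ...]:
    """Read a motif set from TSV with columns (name, pattern)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "pattern"} <= set(df.columns):
        raise ValueError(f"{path}: motif TSV needs 'name' and 'pattern' columns")
    return tuple(Motif(r["name"], r["pattern"].upper()) for _, r in df.iterrows())


def write_motifs_tsv(motifs: Sequence[Motif], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\tpattern\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.pattern}\n")
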