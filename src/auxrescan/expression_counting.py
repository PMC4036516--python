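"""Strand-specific read-to-gene counting with a multimapper cap, and RPKM.

A read is assigned to every gene whose exon model it overlaps by at least
one base (so reads partially covering a UTR boundary still count).  Reads
hitting more than ``max_targets`` distinct genes (20 by default) are
discarded; reads within the cap contribute a full count of 1 to each target
gene, split into sense and antisense buckets according to the library
orientation.  RPKM (reads per kilobase of exon model per million mapped
reads) uses the union exon length of the representative gene model and the
total number of reads mapped to the genome, including reads that overlap no
gene.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a read: 1-based inclusive blocks on one strand."""

    read_id: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.blocks:
            if s > e or s <= prev_end:
                raise ValueError(
                    f"read {self.read_id}: blocks must be sorted, non-overlapping"
                )
            prev_end = e


@dataclass
class GeneCounts:
    gene_id: str
    sense_count: float = 0.0
    antisense_count: float = 0.0


@dataclass(frozen=True)
class ExpressionRow:
    gene_id: str
    exon_model_length: int
    count: float
    rpkm: float


def read_alignments_tsv(path: str | os.PathLike) -> Iterator[AlignmentRecord]:
    """Read alignments from TSV: read_id, chrom, strand, blocks.

    ``blocks`` is a ';'-separated list of 1-based inclusive 'start-end'
    intervals.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("read_id", "chrom", "strand", "blocks"):
            if name not in idx:
                raise ValueError(f"{path}: alignment TSV missing column {name!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            blocks = tuple(
                tuple(int(x) for x in b.split("-"))
                for b in parts[idx["blocks"]].split(";")
            )
            yield AlignmentRecord(
                read_id=parts[idx["read_id"]],
                chrom=parts[idx["chrom"]],
                blocks=blocks,
                strand=parts[idx["strand"]],
            )


def read_alignments_sam(path: str | os.PathLike) -> Iterator[AlignmentRecord]:
    """Read alignments from SAM/BAM via pysam (unmapped records skipped)."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            blocks = tuple((s + 1, e) for s, e in rec.get_blocks())
            yield AlignmentRecord(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                blocks=blocks,
                strand="-" if rec.is_reverse else "+",
            )


def write_alignments_tsv(
    records: Iterable[AlignmentRecord], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstrand\tblocks\n")
        for r in records:
            blocks = ";".join(f"{s}-{e}" for s, e in r.blocks)
            fh.write(f"{r.read_id}\t{r.chrom}\t{r.strand}\t{blocks}\n")


def group_by_read(
    records: Iterable[AlignmentRecord],
) -> Iterator[tuple[str, list[AlignmentRecord]]]:
    """Group consecutive records by read id (records must be pre-grouped)."""
    for read_id, group in itertools.groupby(records, key=lambda r: r.read_id):
        yield read_id, list(group)


def exon_model_lengths(genes: Iterable[GeneModel]) -> dict[str, int]:
    """Union exon length per gene (merged, 1-based inclusive spans)."""
    out = {}
    for g in genes:
        total, cur_s, cur_e = 0, None, None
        for s, e in sorted(g.exon_spans):
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s + 1
        out[g.gene_id] = total
    return out


def _build_exon_index(genes: Iterable[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.exon_spans:
            tree[s : e + 1] = g  # half-open
    return trees


def assign_reads(
    records: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    max_targets: int = 20,
    orientation: str = "forward",
    min_overlap: int = 1,
) -> tuple[dict[str, GeneCounts], dict[str, int]]:
    """Assign grouped alignment records to genes under the multimapper cap.

    ``orientation='forward'`` means a read on the gene's strand is sense;
    ``'reverse'`` flips the convention (dUTP-style libraries).  Returns the
    per-gene counts and a stats dict with ``total_reads`` (reads mapped to
    the genome, the RPKM denominator), ``reads_over_cap`` and
    ``reads_no_gene``.
    """
    if orientation not in ("forward", "reverse"):
        raise ValueError("orientation must be 'forward' or 'reverse'")
    trees = _build_exon_index(genes)
    gene_by_id = {g.gene_id: g for g in genes}
    counts = {g.gene_id: GeneCounts(g.gene_id) for g in genes}
    stats = {"total_reads": 0, "reads_over_cap": 0, "reads_no_gene": 0,
             "reads_unknown_chrom": 0}

    for read_id, group in group_by_read(records):
        known = []
        for rec in group:
            if rec.chrom not in trees:
                logger.warning(
                    "read %s: unknown chromosome %s; alignment skipped",
                    read_id, rec.chrom,
                )
                stats["reads_unknown_chrom"] += 1
                continue
            known.append(rec)
        if not known and group:
            continue
        stats["total_reads"] += 1

        targets: dict[str, str] = {}  # gene_id -> read strand at that locus
        for rec in known:
            tree = trees[rec.chrom]
            for s, e in rec.blocks:
                for iv in tree.overlap(s, e + 1):
                    g = iv.data
                    ov = min(e, iv.end - 1) - max(s, iv.begin) + 1
                    if ov >= min_overlap:
                        targets.setdefault(g.gene_id, rec.strand)
        if not targets:
            stats["reads_no_gene"] += 1
            continue
        if len(targets) > max_targets:
            stats["reads_over_cap"] += 1
            continue
        for gid, read_strand in targets.items():
            same = read_strand == gene_by_id[gid].strand
            sense = same if orientation == "forward" else not same
            if sense:
                counts[gid].sense_count += 1
            else:
                counts[gid].antisense_count += 1
    return counts, stats


def compute_rpkm(
    counts: Mapping[str, float],
    exon_lengths: Mapping[str, int],
    total_mapped_reads: int,
) -> list[ExpressionRow]:
    """RPKM = count / (exon_model_length/1e3) / (total_mapped/1e6)."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    rows = []
    for gid in counts:
        if gid not in exon_lengths:
            raise ValueError(f"missing exon model length for gene {gid}")
        length = exon_lengths[gid]
        if length <= 0:
            raise ValueError(f"gene {gid}: exon model length must be > 0")
        c = counts[gid]
        rpkm = c / (length / 1e3) / (total_mapped_reads / 1e6)
        rows.append(ExpressionRow(gid, length, c, rpkm))
    return rows


def average_rpkm(replicates: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Arithmetic mean RPKM per gene across replicate tables.

    A gene absent from some replicate contributes 0 there (logged)."""
    if not replicates:
        raise ValueError("need at least one replicate")
    all_genes = sorted(set().union(*[set(r) for r in replicates]))
    out = {}
    for g in all_genes:
        vals = []
        for i, rep in enumerate(replicates):
            if g not in rep:
                logger.warning("gene %s missing from replicate %d; treated as 0", g, i)
            vals.append(rep.get(g, 0.0))
        out[g] = sum(vals) / len(vals)
    return out


def expression_frame(
    counts: Mapping[str, GeneCounts],
    exon_lengths: Mapping[str, int],
    total_mapped_reads: int,
    strand: str = "sense",
) -> pd.DataFrame:
    """Tabulate counts and RPKM (RPKM computed on the chosen strand bucket)."""
    chosen = {
        gid: (gc.sense_count if strand == "sense" else gc.antisense_count)
        for gid, gc in counts.items()
    }
    rows = compute_rpkm(chosen, exon_lengths, total_mapped_reads)
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "sense_count": [counts[r.gene_id].sense_count for r in rows],
            "antisense_count": [counts[r.gene_id].antisense_count for r in rows],
            "exon_model_length": [r.exon_model_length for r in rows],
            "rpkm": [r.rpkm for r in rows],
        }
    )
    return df.sort_values("gene_id", ignore_index=True)
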