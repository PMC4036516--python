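"""Genome FASTA / GFF3 input and upstream (promoter) region extraction.

Promoters are defined relative to the start codon: the window covers up to
``max_len`` bases 5' of the first base of the start codon on the gene's
coding strand, truncated where it would run into any other gene's span
(on either strand) or off the chromosome end.  Coordinates are handled
internally as 0-based half-open and converted to 1-based inclusive only
at the file-format boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


@dataclass(frozen=True)
class GeneModel:
    """A gene with one representative mRNA (the longest-CDS isoform).

    ``cds_start`` is the genomic coordinate (1-based) of the first base of
    the start codon on the coding strand: the leftmost CDS base for ``+``
    genes and the rightmost for ``-`` genes.  ``gene_span`` and
    ``exon_spans`` are 1-based inclusive intervals.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    gene_span: tuple[int, int]
    exon_spans: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        s, e = self.gene_span
        if s > e:
            raise ValueError(f"{self.gene_id}: gene_span start > end")
        if not (s <= self.cds_start <= e):
            raise ValueError(f"{self.gene_id}: cds_start outside gene_span")
        for xs, xe in self.exon_spans:
            if not (s <= xs <= xe <= e):
                raise ValueError(f"{self.gene_id}: exon outside gene_span")


@dataclass(frozen=True)
class PromoterRegion:
    """An extracted upstream sequence, 5'->3' on the gene's coding strand.

    ``genomic_interval`` is 1-based inclusive; for length-0 promoters it is
    ``None``.  ``truncated`` is True only when a neighbouring gene (recorded
    in ``truncating_gene_id``) shortened the window; running off the
    chromosome edge does not set the flag.
    """

    gene_id: str
    sequence: str
    genomic_interval: Optional[tuple[int, int]]
    truncated: bool = False
    truncating_gene_id: Optional[str] = None
    chrom: str = ""
    strand: str = "+"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.truncated != (self.truncating_gene_id is not None):
            raise ValueError(
                f"{self.gene_id}: truncated flag and truncating_gene_id disagree"
            )
        if self.genomic_interval is not None:
            a, b = self.genomic_interval
            if b - a + 1 != len(self.sequence):
                raise ValueError(f"{self.gene_id}: interval/sequence length mismatch")


def read_genome(fasta_path: str | os.PathLike) -> dict[str, str]:
    """Read a genome FASTA into a dict of chrom -> uppercase sequence.

    Characters outside {A, C, G, T, N} (after uppercasing) are mapped to N.
    Raises on a missing file, an empty file, or duplicate record ids.
    """
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(str(fasta_path))
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate FASTA record id: {rec.id}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _VALID:
            seq = "".join(c if c in _VALID else "N" for c in seq)
        genome[rec.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return genome


def _check_gff3_lines(gff3_path: str | os.PathLike) -> None:
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{gff3_path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated columns"
                )


def read_annotation(gff3_path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3, one representative mRNA per gene.

    The representative mRNA is the one with the longest total CDS length
    (ties broken by mRNA id).  Genes without any CDS are skipped with a
    logged warning.
    """
    if not os.path.exists(gff3_path):
        raise FileNotFoundError(str(gff3_path))
    _check_gff3_lines(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    n_skipped = 0
    for gene in db.features_of_type("gene"):
        best = None  # (cds_len, mrna_id, cds_spans, exon_spans)
        for mrna in db.children(gene, featuretype="mRNA"):
            cds = [(c.start, c.end) for c in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            exons = [(x.start, x.end) for x in db.children(mrna, featuretype="exon")]
            cds_len = sum(e - s + 1 for s, e in cds)
            key = (cds_len, mrna.id)
            if best is None or (key[0], key[1]) > (best[0], best[1]):
                best = (cds_len, mrna.id, sorted(cds), sorted(exons or cds))
        if best is None:
            logger.warning("gene %s has no CDS; skipped", gene.id)
            n_skipped += 1
            continue
        _, _, cds_spans, exon_spans = best
        if gene.strand == "+":
            cds_start = cds_spans[0][0]
        else:
            cds_start = cds_spans[-1][1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_start=cds_start,
                gene_span=(gene.start, gene.end),
                exon_spans=tuple(exon_spans),
            )
        )
    if n_skipped:
        logger.warning("skipped %d genes without CDS", n_skipped)
    return models


_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def extract_upstream(
    genes: Iterable[GeneModel],
    genome: Mapping[str, str],
    max_len: int = 1000,
) -> list[PromoterRegion]:
    """Extract each gene's upstream region, up to ``max_len`` bases.

    The window runs 5' from the base immediately before the start codon and
    stops at the first base covered by any other gene's span (either strand)
    or at the chromosome edge.  ``-``-strand windows are reverse-complemented
    so all promoters read 5'->3' on the coding strand.  Genes whose start
    codon abuts a neighbour yield a length-0 promoter.
    """
    genes = list(genes)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    promoters: list[PromoterRegion] = []
    n_zero = 0
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(
                f"chromosome {g.chrom!r} for gene {g.gene_id} not in genome"
            )
        chrom_seq = genome[g.chrom]
        chrom_len = len(chrom_seq)
        others = [o for o in by_chrom[g.chrom] if o.gene_id != g.gene_id]

        trunc_id: Optional[str] = None
        if g.strand == "+":
            # nearest foreign covered base at or left of cds_start - 1
            lo_limit = 0  # first allowed genomic position (1-based) minus 1
            for o in others:
                os_, oe = o.gene_span
                if os_ <= g.cds_start - 1:
                    covered = min(oe, g.cds_start - 1)
                    if covered > lo_limit:
                        lo_limit, trunc_id = covered, o.gene_id
            length = g.cds_start - 1 - lo_limit
            if length > max_len:
                length, trunc_id = max_len, None
            if length < 0:
                length = 0
            interval = (g.cds_start - length, g.cds_start - 1) if length else None
            seq = (
                chrom_seq[g.cds_start - 1 - length : g.cds_start - 1]
                if length
                else ""
            )
        else:
            hi_limit = chrom_len + 1  # first disallowed genomic position
            for o in others:
                os_, oe = o.gene_span
                if oe >= g.cds_start + 1:
                    covered = max(os_, g.cds_start + 1)
                    if covered < hi_limit:
                        hi_limit, trunc_id = covered, o.gene_id
            length = hi_limit - g.cds_start - 1
            if length > max_len:
                length, trunc_id = max_len, None
            if length < 0:
                length = 0
            interval = (g.cds_start + 1, g.cds_start + length) if length else None
            seq = (
                reverse_complement(chrom_seq[g.cds_start : g.cds_start + length])
                if length
                else ""
            )
        if length == 0:
            n_zero += 1
        promoters.append(
            PromoterRegion(
                gene_id=g.gene_id,
                sequence=seq,
                genomic_interval=interval,
                truncated=trunc_id is not None,
                truncating_gene_id=trunc_id,
                chrom=g.chrom,
                strand=g.strand,
            )
        )
    if n_zero:
        logger.info("%d genes yielded length-0 promoters", n_zero)
    return promoters


def write_promoters_fasta(
    promoters: Iterable[PromoterRegion], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            if p.length == 0:
                continue
            fh.write(f">{p.gene_id}\n{p.sequence}\n")


def read_promoters_fasta(path: str | os.PathLike) -> list[PromoterRegion]:
    """Read promoters back from FASTA (provenance fields are unknown)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(
            PromoterRegion(
                gene_id=rec.id,
                sequence=str(rec.seq).upper(),
                genomic_interval=None,
            )
        )
    return out


def write_promoter_report(
    promoters: Iterable[PromoterRegion], path: str | os.PathLike
) -> None:
    """TSV report: one row per gene with interval and truncation provenance."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tchrom\tstart\tend\tstrand\tlength\ttruncated\t"
            "truncating_gene_id\n"
        )
        for p in promoters:
            start, end = p.genomic_interval or ("", "")
            fh.write(
                f"{p.gene_id}\t{p.chrom}\t{start}\t{end}\t{p.strand}\t"
                f"{p.length}\t{str(p.truncated).lower()}\t"
                f"{p.truncating_gene_id or ''}\n"
            )
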