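"""Synthetic inputs with known ground truth for every pipeline stage.

Generates, reproducibly from a seed: genomes with GFF3 gene models laid out
so a configurable fraction of genes has a neighbour within 1 kb (exercising
promoter truncation); promoter cohorts over an i.i.d. base composition with
AuxRE pairs planted in a signal subset; paired differential-expression
tables with a configured shared-significant subset; MapMan-BIN-style
category maps with planted enrichment; and strand-specific alignment
records with a controlled multimapping spectrum (including reads hitting
exactly the multimapper cap and one past it).

Background promoters use order-0 (i.i.d.) bases, matching the
mononucleotide shuffle null; planting overwrites bases in place, so signal
promoters keep their length and only their composition shifts slightly —
acceptable because the null is recomputed per promoter from its own
sequence.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .expression_counting import AlignmentRecord, write_alignments_tsv
from .genome_io import GeneModel, PromoterRegion, reverse_complement
from .pairscan import DEFAULT_MOTIFS, MOTIF_LEN, Motif

_BASES = "ACGT"


@dataclass(frozen=True)
class DEConfig:
    """Shape of the two simulated DE comparisons (adjusted-P level only)."""

    n_de_shared: int = 50
    n_de_unique_a: int = 25
    n_de_unique_b: int = 25
    alpha: float = 0.05
    sig_margin: float = 0.9  # significant p drawn from U(0, alpha*sig_margin)
    n_at_alpha: int = 0      # boundary genes with p == alpha in both tables
    p_down: float = 0.7


@dataclass(frozen=True)
class AlignmentConfig:
    reads_per_gene: int = 20
    read_length: int = 50
    multimap_degrees: tuple[int, ...] = (2, 5, 20, 21)
    reads_per_degree: int = 2
    n_intergenic_reads: int = 10
    orientation: str = "forward"
    antisense_fraction: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 200
    chrom_length: Optional[int] = None  # None: sized to fit the layout
    promoter_len: int = 1000
    base_composition: tuple[float, float, float, float] = (0.33, 0.17, 0.17, 0.33)
    signal_fraction: float = 0.1
    planted_pairs_per_signal_gene: int = 2
    planted_gap: int = 10
    neighbor_close_fraction: float = 0.25
    n_categories: int = 136
    n_enriched_categories: int = 1
    enrichment_odds: float = 10.0
    de: DEConfig = field(default_factory=DEConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        if not (0 <= self.signal_fraction <= 1):
            raise ValueError("signal_fraction must be in [0, 1]")
        if self.planted_gap > 20:
            raise ValueError("planted_gap must be <= 20")


@dataclass
class GroundTruth:
    """Everything the generators planted, keyed the way outputs are scored."""

    signal_gene_ids: list[str] = field(default_factory=list)
    planted_pairs: dict[str, list[dict]] = field(default_factory=dict)
    expected_promoters: dict[str, dict] = field(default_factory=dict)
    shared_de: list[str] = field(default_factory=list)
    unique_de_a: list[str] = field(default_factory=list)
    unique_de_b: list[str] = field(default_factory=list)
    enriched_category_ids: list[str] = field(default_factory=list)
    read_targets: dict[str, list[str]] = field(default_factory=dict)
    expected_counts: dict[str, dict] = field(default_factory=dict)
    total_mapped_reads: int = 0

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def random_sequence(
    length: int, composition: Sequence[float], rng: np.random.Generator
) -> str:
    idx = rng.choice(4, size=length, p=np.asarray(composition, dtype=float))
    return "".join(_BASES[i] for i in idx)


# ---------------------------------------------------------------------------
# promoter cohorts

def simulate_promoters(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[PromoterRegion], GroundTruth]:
    """Background promoter cohort plus planted signal subset.

    round(signal_fraction * n_genes) promoters, chosen at random, receive
    ``planted_pairs_per_signal_gene`` motif pairs each; the rest stay pure
    i.i.d. background.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    promoters = [
        PromoterRegion(
            gene_id=f"g{i:05d}",
            sequence=random_sequence(config.promoter_len, config.base_composition, rng),
            genomic_interval=None,
        )
        for i in range(config.n_genes)
    ]
    truth = GroundTruth()
    n_signal = int(round(config.signal_fraction * config.n_genes))
    signal_idx = rng.choice(config.n_genes, size=n_signal, replace=False)
    signal_ids = {promoters[i].gene_id for i in signal_idx}
    promoters = plant_motif_pairs(promoters, config, rng, signal_ids, truth)
    return promoters, truth


def plant_motif_pairs(
    promoters: Sequence[PromoterRegion],
    config: SimConfig,
    rng: np.random.Generator,
    signal_ids: Optional[set[str]] = None,
    truth: Optional[GroundTruth] = None,
    motifs: Sequence[Motif] = DEFAULT_MOTIFS,
) -> list[PromoterRegion]:
    """Overwrite motif pairs into the signal promoters, recording coordinates.

    Each pair is two motif instances (independently sampled from the motif
    set) separated by exactly ``planted_gap`` bases, written at a random
    admissible offset; multiple pairs per promoter go into disjoint equal
    segments so planted pairs never overlap each other.
    """
    truth = truth if truth is not None else GroundTruth()
    if signal_ids is None:
        n_signal = int(round(config.signal_fraction * len(promoters)))
        idx = rng.choice(len(promoters), size=n_signal, replace=False)
        signal_ids = {promoters[i].gene_id for i in idx}

    pair_span = 2 * MOTIF_LEN + config.planted_gap
    n_pairs = config.planted_pairs_per_signal_gene
    out = []
    for p in promoters:
        if p.gene_id not in signal_ids:
            out.append(p)
            continue
        if len(p.sequence) < n_pairs * pair_span:
            raise ValueError(
                f"promoter {p.gene_id} too short to plant {n_pairs} pairs"
            )
        seg = len(p.sequence) // n_pairs
        seq = list(p.sequence)
        planted = []
        for j in range(n_pairs):
            off = int(seg * j + rng.integers(0, seg - pair_span + 1))
            m_a = motifs[rng.integers(len(motifs))]
            m_b = motifs[rng.integers(len(motifs))]
            seq[off : off + MOTIF_LEN] = m_a.pattern
            b_start = off + MOTIF_LEN + config.planted_gap
            seq[b_start : b_start + MOTIF_LEN] = m_b.pattern
            planted.append(
                {
                    "start_a": off,
                    "motif_a": m_a.name,
                    "start_b": b_start,
                    "motif_b": m_b.name,
                    "gap": config.planted_gap,
                }
            )
        out.append(dataclasses.replace(p, sequence="".join(seq)))
        truth.signal_gene_ids.append(p.gene_id)
        truth.planted_pairs[p.gene_id] = planted
    return out


# ---------------------------------------------------------------------------
# genome + annotation

def simulate_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Lay genes on one chromosome with a mix of near and far neighbours.

    A ``neighbor_close_fraction`` of intergenic gaps is drawn below 1 kb so
    the downstream gene's promoter is truncated; ground truth records each
    gene's expected promoter length and truncating neighbour.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = GroundTruth()
    chrom = "chr1"

    genes: list[GeneModel] = []
    pos = int(rng.integers(config.promoter_len + 100, config.promoter_len + 1000))
    layout = []
    for i in range(config.n_genes):
        gene_len = int(rng.integers(600, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        utr = int(rng.integers(0, 101))
        s, e = pos, pos + gene_len - 1
        cds_start = s + utr if strand == "+" else e - utr
        # one or two exons covering the span
        if gene_len > 900 and rng.random() < 0.5:
            mid = s + gene_len // 2
            intron = int(rng.integers(60, 200))
            exons = ((s, mid), (mid + intron + 1, e))
            e = exons[-1][1]
        else:
            exons = ((s, e),)
        genes.append(
            GeneModel(
                gene_id=f"g{i:05d}",
                chrom=chrom,
                strand=strand,
                cds_start=cds_start,
                gene_span=(s, e),
                exon_spans=exons,
            )
        )
        layout.append((s, e))
        if rng.random() < config.neighbor_close_fraction:
            gap = int(rng.integers(50, 900))
        else:
            gap = int(rng.integers(config.promoter_len + 101, 3000))
        pos = e + 1 + gap

    needed = layout[-1][1] + config.promoter_len + 200
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValueError(
            f"chrom_length {config.chrom_length} cannot hold {config.n_genes} "
            f"genes (needs >= {needed})"
        )
    chrom_len = config.chrom_length or needed
    sequence = random_sequence(chrom_len, config.base_composition, rng)
    genome = {chrom: sequence}

    # expected promoter geometry, from the layout
    for i, g in enumerate(genes):
        if g.strand == "+":
            prev_end = layout[i - 1][1] if i > 0 else 0
            dist = g.cds_start - 1 - prev_end
            neighbor = genes[i - 1].gene_id if i > 0 else None
        else:
            next_start = layout[i + 1][0] if i + 1 < len(genes) else chrom_len + 1
            dist = next_start - g.cds_start - 1
            neighbor = genes[i + 1].gene_id if i + 1 < len(genes) else None
        exp_len = min(config.promoter_len, max(dist, 0))
        truth.expected_promoters[g.gene_id] = {
            "length": int(exp_len),
            "truncated": bool(exp_len < config.promoter_len and neighbor is not None
                              and dist < config.promoter_len),
            "truncating_gene_id": neighbor
            if (exp_len < config.promoter_len and neighbor is not None
                and dist < config.promoter_len)
            else None,
        }
    return genome, genes, truth


def write_genome_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/mRNA/exon/CDS features (one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.gene_span
            common = f"{g.chrom}\tsim"
            fh.write(
                f"{common}\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{common}\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for xs, xe in g.exon_spans:
                fh.write(
                    f"{common}\texon\t{xs}\t{xe}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            # CDS: coding side of the start codon, clipped to exons
            if g.strand == "+":
                coding = (g.cds_start, e)
            else:
                coding = (s, g.cds_start)
            for xs, xe in g.exon_spans:
                cs, ce = max(xs, coding[0]), min(xe, coding[1])
                if cs <= ce:
                    fh.write(
                        f"{common}\tCDS\t{cs}\t{ce}\t.\t{g.strand}\t0\t"
                        f"Parent={mrna}\n"
                    )


# ---------------------------------------------------------------------------
# DE tables and category maps

def simulate_de_tables(
    gene_ids: Sequence[str],
    de: DEConfig,
    rng: np.random.Generator,
    truth: Optional[GroundTruth] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two DE tables with an exact shared-significant subset.

    Exactly ``n_de_shared`` genes get adjusted P < alpha in both tables,
    ``n_de_unique_*`` in one table only; ``n_at_alpha`` genes sit exactly at
    the alpha boundary in both (excluded by the strict-< rule); all other
    genes are non-significant everywhere.
    """
    truth = truth if truth is not None else GroundTruth()
    gene_ids = list(gene_ids)
    need = de.n_de_shared + de.n_de_unique_a + de.n_de_unique_b + de.n_at_alpha
    if need > len(gene_ids):
        raise ValueError("not enough genes for the requested DE design")
    picked = rng.choice(len(gene_ids), size=need, replace=False)
    picked_ids = [gene_ids[i] for i in picked]
    shared = picked_ids[: de.n_de_shared]
    ua = picked_ids[de.n_de_shared : de.n_de_shared + de.n_de_unique_a]
    ub = picked_ids[
        de.n_de_shared + de.n_de_unique_a : de.n_de_shared + de.n_de_unique_a
        + de.n_de_unique_b
    ]
    boundary = picked_ids[need - de.n_at_alpha :] if de.n_at_alpha else []

    def sig_p():
        return float(rng.uniform(1e-8, de.alpha * de.sig_margin))

    def nonsig_p():
        return float(rng.uniform(de.alpha * 1.01, 1.0))

    direction = {
        g: ("down" if rng.random() < de.p_down else "up") for g in gene_ids
    }
    rows_a, rows_b = [], []
    shared_set, ua_set, ub_set, bd_set = set(shared), set(ua), set(ub), set(boundary)
    for g in gene_ids:
        if g in bd_set:
            pa = pb = de.alpha
        else:
            pa = sig_p() if g in shared_set or g in ua_set else nonsig_p()
            pb = sig_p() if g in shared_set or g in ub_set else nonsig_p()
        rows_a.append((g, pa, direction[g]))
        rows_b.append((g, pb, direction[g]))
    cols = ["gene_id", "padj", "direction"]
    table_a = pd.DataFrame(rows_a, columns=cols).set_index("gene_id")
    table_b = pd.DataFrame(rows_b, columns=cols).set_index("gene_id")
    truth.shared_de = sorted(shared)
    truth.unique_de_a = sorted(ua)
    truth.unique_de_b = sorted(ub)
    return table_a, table_b, truth


def simulate_category_map(
    gene_ids: Sequence[str],
    de_genes: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
    truth: Optional[GroundTruth] = None,
) -> tuple[dict[str, set[str]], dict[str, str], GroundTruth]:
    """Category map with planted enrichment.

    The first ``n_enriched_categories`` categories draw their members with
    weight ``enrichment_odds`` on DE genes; the rest draw uniformly.
    """
    truth = truth if truth is not None else GroundTruth()
    gene_ids = list(gene_ids)
    de_set = set(de_genes)
    weights = np.array([config.enrichment_odds if g in de_set else 1.0
                        for g in gene_ids])
    cmap: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for c in range(config.n_categories):
        cid = f"BIN{c + 1:03d}"
        if c < config.n_enriched_categories:
            # planted categories need enough members for their enrichment to
            # be identifiable; background sizes span the full range
            size = min(int(rng.integers(15, 31)), len(gene_ids))
            p = weights / weights.sum()
            members = rng.choice(len(gene_ids), size=size, replace=False, p=p)
            truth.enriched_category_ids.append(cid)
            labels[cid] = f"planted enriched category {c + 1}"
        else:
            size = min(int(rng.integers(5, 31)), len(gene_ids))
            members = rng.choice(len(gene_ids), size=size, replace=False)
            labels[cid] = f"background category {c + 1}"
        cmap[cid] = {gene_ids[i] for i in members}
    return cmap, labels, truth


# ---------------------------------------------------------------------------
# alignments

def simulate_alignments(
    genes: Sequence[GeneModel],
    config: AlignmentConfig,
    rng: np.random.Generator,
    truth: Optional[GroundTruth] = None,
) -> tuple[list[AlignmentRecord], GroundTruth]:
    """Alignment records with known per-read target genes.

    Emits unique reads per gene, multimappers of the configured degrees
    (including degrees at and past the 20-gene cap), and intergenic reads
    that map to the genome but to no gene.  Reads are sense with respect to
    their target genes except for a configurable antisense fraction of the
    unique reads.
    """
    truth = truth if truth is not None else GroundTruth()
    records: list[AlignmentRecord] = []
    expected: dict[str, dict] = {
        g.gene_id: {"sense": 0, "antisense": 0} for g in genes
    }

    def read_strand(gene_strand: str, sense: bool) -> str:
        same = sense if config.orientation == "forward" else not sense
        return gene_strand if same else ("-" if gene_strand == "+" else "+")

    def block_in(g: GeneModel, rng) -> tuple[int, int]:
        xs, xe = g.exon_spans[int(rng.integers(len(g.exon_spans)))]
        blen = min(config.read_length, xe - xs + 1)
        start = int(rng.integers(xs, xe - blen + 2))
        return start, start + blen - 1

    n_reads = 0
    for g in genes:
        for i in range(config.reads_per_gene):
            sense = rng.random() >= config.antisense_fraction
            rid = f"u_{g.gene_id}_{i}"
            records.append(
                AlignmentRecord(rid, g.chrom, (block_in(g, rng),),
                                read_strand(g.strand, sense))
            )
            truth.read_targets[rid] = [g.gene_id]
            expected[g.gene_id]["sense" if sense else "antisense"] += 1
            n_reads += 1

    for d in config.multimap_degrees:
        if d > len(genes):
            raise ValueError(f"multimap degree {d} exceeds gene count")
        for i in range(config.reads_per_degree):
            rid = f"mm{d}_{i}"
            idx = rng.choice(len(genes), size=d, replace=False)
            for j in idx:
                g = genes[j]
                records.append(
                    AlignmentRecord(rid, g.chrom, (block_in(g, rng),),
                                    read_strand(g.strand, True))
                )
            truth.read_targets[rid] = sorted(genes[j].gene_id for j in idx)
            if d <= 20:
                for j in idx:
                    expected[genes[j].gene_id]["sense"] += 1
            n_reads += 1

    # intergenic reads: between gene spans, overlapping no gene
    spans = sorted(g.gene_span for g in genes)
    gaps = []
    for (s1, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 - e1 - 1 >= config.read_length + 2:
            gaps.append((e1 + 2, s2 - config.read_length - 1))
    chrom = genes[0].chrom if genes else "chr1"
    for i in range(config.n_intergenic_reads):
        if not gaps:
            break
        lo, hi = gaps[int(rng.integers(len(gaps)))]
        start = int(rng.integers(lo, hi + 1))
        rid = f"bg_{i}"
        records.append(
            AlignmentRecord(
                rid, chrom, ((start, start + config.read_length - 1),),
                "+" if rng.random() < 0.5 else "-",
            )
        )
        truth.read_targets[rid] = []
        n_reads += 1

    truth.expected_counts = expected
    truth.total_mapped_reads = n_reads
    return records, truth


# ---------------------------------------------------------------------------
# one-call fixture generation

def run_simulation(config: SimConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Emit a complete fixture set (FASTA, GFF3, TSVs, ground-truth JSON)."""
    from .enrichment import write_category_map
    from .genome_io import extract_upstream, write_promoters_fasta
    from .pairscan import write_motifs_tsv

    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    genome, genes, truth = simulate_genome(config, rng)
    write_genome_fasta(genome, os.path.join(outdir, "genome.fasta"))
    write_gff3(genes, os.path.join(outdir, "annotation.gff3"))
    write_motifs_tsv(DEFAULT_MOTIFS, os.path.join(outdir, "motifs.tsv"))

    # promoters with planted signal (planting happens at the promoter level,
    # so promoters.fasta carries the signal; genome.fasta stays background)
    promoters = extract_upstream(genes, genome, max_len=config.promoter_len)
    pair_span = 2 * MOTIF_LEN + config.planted_gap
    min_len = config.planted_pairs_per_signal_gene * pair_span
    eligible = [p for p in promoters if p.length >= min_len]
    n_signal = int(round(config.signal_fraction * len(eligible)))
    sig_idx = rng.choice(len(eligible), size=n_signal, replace=False)
    signal_ids = {eligible[i].gene_id for i in sig_idx}
    promoters = plant_motif_pairs(promoters, config, rng, signal_ids, truth)
    write_promoters_fasta(promoters, os.path.join(outdir, "promoters.fasta"))

    gene_ids = [g.gene_id for g in genes]
    table_a, table_b, truth = simulate_de_tables(gene_ids, config.de, rng, truth)
    table_a.to_csv(os.path.join(outdir, "de_a.tsv"), sep="\t")
    table_b.to_csv(os.path.join(outdir, "de_b.tsv"), sep="\t")

    cmap, labels, truth = simulate_category_map(
        gene_ids, truth.shared_de, config, rng, truth
    )
    write_category_map(cmap, os.path.join(outdir, "categories.tsv"), labels)
    with open(os.path.join(outdir, "universe.txt"), "w") as fh:
        fh.write("\n".join(gene_ids) + "\n")

    records, truth = simulate_alignments(genes, config.alignment, rng, truth)
    write_alignments_tsv(records, os.path.join(outdir, "alignments.tsv"))
    truth.to_json(os.path.join(outdir, "ground_truth.json"))
    return truth
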