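import pytest

from auxrescan import genome_io as gio
from conftest import make_gene


class TestReadGenome:
    def test_basic_parse_and_case(self, tmp_path):
        f = tmp_path / "g.fasta"
        f.write_text(">c1\nacgt\n>c2\nACGTN\n")
        genome = gio.read_genome(f)
        assert genome == {"c1": "ACGT", "c2": "ACGTN"}

    def test_non_acgtn_mapped_to_n(self, tmp_path):
        f = tmp_path / "g.fasta"
        f.write_text(">c1\nACRYGT\n")
        assert gio.read_genome(f)["c1"] == "ACNNGT"

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "g.fasta"
        f.write_text(">c1\nACGT\n>c1\nGGGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_genome(f)

    def test_missing_and_empty_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            gio.read_genome(tmp_path / "absent.fasta")
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            gio.read_genome(empty)


class TestReadAnnotation:
    def test_cds_start_convention_by_strand(self, toy_genome_files):
        _, gff = toy_genome_files
        genes = {g.gene_id: g for g in gio.read_annotation(gff)}
        # + strand: leftmost CDS base; - strand: rightmost CDS base
        assert genes["geneA"].cds_start == 2001
        assert genes["geneB"].cds_start == 3500
        assert genes["geneA"].strand == "+"
        assert genes["geneB"].strand == "-"

    def test_longest_cds_isoform_chosen(self, tmp_path):
        gff = tmp_path / "iso.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tt\tgene\t101\t700\t.\t+\t.\tID=g\n"
            "c1\tt\tmRNA\t101\t700\t.\t+\t.\tID=g.1;Parent=g\n"
            "c1\tt\texon\t101\t700\t.\t+\t.\tParent=g.1\n"
            "c1\tt\tCDS\t151\t300\t.\t+\t0\tParent=g.1\n"   # 150 nt
            "c1\tt\tmRNA\t101\t700\t.\t+\t.\tID=g.2;Parent=g\n"
            "c1\tt\texon\t101\t700\t.\t+\t.\tParent=g.2\n"
            "c1\tt\tCDS\t101\t400\t.\t+\t0\tParent=g.2\n"   # 300 nt
        )
        (gene,) = gio.read_annotation(gff)
        assert gene.cds_start == 101  # from the 300 nt CDS isoform

    def test_gene_without_cds_skipped(self, tmp_path, caplog):
        gff = tmp_path / "nocds.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tt\tgene\t101\t400\t.\t+\t.\tID=g\n"
            "c1\tt\tmRNA\t101\t400\t.\t+\t.\tID=g.1;Parent=g\n"
            "c1\tt\texon\t101\t400\t.\t+\t.\tParent=g.1\n"
        )
        assert gio.read_annotation(gff) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text("##gff-version 3\nc1\tt\tgene\t1\t10\n")
        with pytest.raises(ValueError, match="line 2"):
            gio.read_annotation(gff)


class TestExtractUpstream:
    def test_plus_strand_full_window(self, toy_genome):
        gene = make_gene(cds_start=2001, span=(2001, 2600))
        (p,) = gio.extract_upstream([gene], toy_genome, max_len=1000)
        assert p.genomic_interval == (1001, 2000)
        assert p.length == 1000
        assert not p.truncated
        assert p.sequence == toy_genome["c1"][1000:2000]

    def test_plus_strand_truncated_by_neighbor(self, toy_genome):
        gene = make_gene("g1", cds_start=2001, span=(2001, 2600))
        neighbor = make_gene("g0", cds_start=1200, span=(1200, 1700))
        promoters = {
            p.gene_id: p
            for p in gio.extract_upstream([gene, neighbor], toy_genome)
        }
        p = promoters["g1"]
        # nearest foreign base is at 1700, so the window is [1701, 2000]
        assert p.genomic_interval == (1701, 2000)
        assert p.length == 300
        assert p.truncated and p.truncating_gene_id == "g0"

    def test_minus_strand_reverse_complemented(self, toy_genome):
        gene = make_gene(strand="-", cds_start=50, span=(10, 50))
        (p,) = gio.extract_upstream([gene], toy_genome, max_len=1000)
        assert p.genomic_interval == (51, 1050)
        assert p.length == 1000
        # independent reverse complement of the genomic slice
        expected = gio.reverse_complement(toy_genome["c1"][50:1050])
        assert p.sequence == expected

    def test_zero_length_promoter_when_abutting(self, toy_genome):
        gene = make_gene("g1", cds_start=2001, span=(2001, 2600))
        neighbor = make_gene("g0", cds_start=1200, span=(1200, 2000))
        promoters = {
            p.gene_id: p
            for p in gio.extract_upstream([gene, neighbor], toy_genome)
        }
        assert promoters["g1"].length == 0
        assert promoters["g1"].genomic_interval is None
        assert promoters["g1"].truncated

    def test_chromosome_edge_limits_without_truncation_flag(self, toy_genome):
        gene = make_gene(cds_start=301, span=(301, 900))
        (p,) = gio.extract_upstream([gene], toy_genome)
        assert p.genomic_interval == (1, 300)
        assert p.length == 300
        assert not p.truncated

    def test_missing_chromosome_names_gene(self, toy_genome):
        gene = make_gene("gX", chrom="c9")
        with pytest.raises(KeyError, match="gX"):
            gio.extract_upstream([gene], toy_genome)

    def test_no_promoter_base_inside_foreign_gene_span(self, toy_genome, rng):
        from auxrescan.synthetic_data import SimConfig, simulate_genome

        genome, genes, _ = simulate_genome(SimConfig(seed=7, n_genes=40))
        promoters = gio.extract_upstream(genes, genome)
        spans = {g.gene_id: g.gene_span for g in genes}
        for p in promoters:
            if p.genomic_interval is None:
                continue
            ps, pe = p.genomic_interval
            for gid, (gs, ge) in spans.items():
                if gid == p.gene_id:
                    continue
                assert pe < gs or ps > ge, (p.gene_id, gid)

    def test_strand_symmetry_under_genome_reverse_complement(self, toy_genome):
        """Flipping the chromosome and all annotations leaves promoters fixed."""
        L = len(toy_genome["c1"])
        genes = [
            make_gene("a", cds_start=2001, span=(2001, 2600)),
            make_gene("b", strand="-", cds_start=3500, span=(2801, 3500)),
        ]
        fwd = {p.gene_id: p.sequence
               for p in gio.extract_upstream(genes, toy_genome)}

        flipped_genome = {"c1": gio.reverse_complement(toy_genome["c1"])}

        def flip(g):
            s, e = g.gene_span
            return gio.GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                cds_start=L - g.cds_start + 1,
                gene_span=(L - e + 1, L - s + 1),
                exon_spans=tuple((L - xe + 1, L - xs + 1) for xs, xe in g.exon_spans),
            )

        rev = {p.gene_id: p.sequence
               for p in gio.extract_upstream([flip(g) for g in genes], flipped_genome)}
        assert fwd == rev

    def test_fasta_round_trip(self, toy_genome, tmp_path):
        genes = [make_gene("a", cds_start=2001, span=(2001, 2600))]
        promoters = gio.extract_upstream(genes, toy_genome)
        out = tmp_path / "prom.fasta"
        gio.write_promoters_fasta(promoters, out)
        back = gio.read_promoters_fasta(out)
        assert [(p.gene_id, p.sequence) for p in back] == [
            (p.gene_id, p.sequence) for p in promoters if p.length
        ]

    def test_report_written(self, toy_genome, tmp_path):
        genes = [make_gene("a", cds_start=2001, span=(2001, 2600))]
        promoters = gio.extract_upstream(genes, toy_genome)
        report = tmp_path / "prom.tsv"
        gio.write_promoter_report(promoters, report)
        lines = report.read_text().splitlines()
        assert lines[0].startswith("gene_id\t")
        assert lines[1].split("\t")[:6] == ["a", "c1", "1001", "2000", "+", "1000"]
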