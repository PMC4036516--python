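import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from auxrescan import genome_io as gio
from auxrescan import pairscan as ps
from auxrescan import synthetic_data as sd
from auxrescan.enrichment import intersect_de, read_category_map, read_de_table
from auxrescan.expression_counting import read_alignments_tsv


def dir_hashes(path):
    return {
        f.name: hashlib.sha256(f.read_bytes()).hexdigest()
        for f in sorted(Path(path).iterdir())
    }


class TestDeterminism:
    def test_same_seed_byte_identical_different_seed_differs(self, tmp_path):
        cfg = sd.SimConfig(seed=4, n_genes=120)
        sd.run_simulation(cfg, tmp_path / "a")
        sd.run_simulation(cfg, tmp_path / "b")
        assert dir_hashes(tmp_path / "a") == dir_hashes(tmp_path / "b")
        sd.run_simulation(sd.SimConfig(seed=5, n_genes=120), tmp_path / "c")
        assert dir_hashes(tmp_path / "a") != dir_hashes(tmp_path / "c")


class TestSimulateGenome:
    def test_single_gene_has_full_promoter(self):
        cfg = sd.SimConfig(seed=1, n_genes=1)
        genome, genes, truth = sd.simulate_genome(cfg)
        (p,) = gio.extract_upstream(genes, genome)
        assert p.length == 1000 and not p.truncated

    def test_expected_truncations_realised(self):
        cfg = sd.SimConfig(seed=2, n_genes=60, neighbor_close_fraction=0.5)
        genome, genes, truth = sd.simulate_genome(cfg)
        promoters = gio.extract_upstream(genes, genome)
        assert any(p.truncated for p in promoters)
        for p in promoters:
            exp = truth.expected_promoters[p.gene_id]
            assert p.length == exp["length"], p.gene_id
            assert p.truncated == exp["truncated"], p.gene_id
            assert p.truncating_gene_id == exp["truncating_gene_id"], p.gene_id

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="chrom_length"):
            sd.simulate_genome(sd.SimConfig(seed=1, n_genes=50, chrom_length=10_000))

    def test_emitted_files_validate_with_readers(self, tmp_path):
        sd.run_simulation(sd.SimConfig(seed=3, n_genes=110), tmp_path)
        genome = gio.read_genome(tmp_path / "genome.fasta")
        genes = gio.read_annotation(tmp_path / "annotation.gff3")
        assert len(genes) == 110
        proms = gio.read_promoters_fasta(tmp_path / "promoters.fasta")
        assert proms
        motifs = ps.read_motifs_tsv(tmp_path / "motifs.tsv")
        assert motifs == ps.DEFAULT_MOTIFS
        read_de_table(tmp_path / "de_a.tsv")
        read_category_map(tmp_path / "categories.tsv")
        assert list(read_alignments_tsv(tmp_path / "alignments.tsv"))
        json.loads((tmp_path / "ground_truth.json").read_text())

    def test_annotation_round_trips_through_gff3(self, tmp_path):
        _, genes, _ = sd.simulate_genome(sd.SimConfig(seed=8, n_genes=40))
        path = tmp_path / "g.gff3"
        sd.write_gff3(genes, path)
        back = gio.read_annotation(path)
        key = lambda g: (g.gene_id, g.chrom, g.strand, g.cds_start, g.gene_span,
                         g.exon_spans)
        assert sorted(map(key, back)) == sorted(map(key, genes))


class TestPlanting:
    def test_planted_pair_detected_by_scanner(self, rng):
        cfg = sd.SimConfig(seed=1, n_genes=20, promoter_len=300,
                           signal_fraction=0.5, planted_gap=4)
        promoters, truth = sd.simulate_promoters(cfg)
        by_id = {p.gene_id: p for p in promoters}
        for gid in truth.signal_gene_ids:
            res = ps.scan_promoter(gid, by_id[gid].sequence)
            planted_classes = {
                tuple(sorted((pp["motif_a"], pp["motif_b"])))
                for pp in truth.planted_pairs[gid]
            }
            for pc in planted_classes:
                assert res.pair_counts[pc] >= 1, (gid, pc)
            assert res.total_pairs >= len(truth.planted_pairs[gid])

    def test_planted_coordinates_exact(self):
        cfg = sd.SimConfig(seed=6, n_genes=10, promoter_len=200,
                           signal_fraction=0.3, planted_gap=10,
                           planted_pairs_per_signal_gene=1)
        promoters, truth = sd.simulate_promoters(cfg)
        by_id = {p.gene_id: p for p in promoters}
        motifs = {m.name: m.pattern for m in ps.DEFAULT_MOTIFS}
        for gid, pairs in truth.planted_pairs.items():
            seq = by_id[gid].sequence
            for pp in pairs:
                assert seq[pp["start_a"] : pp["start_a"] + 6] == motifs[pp["motif_a"]]
                assert seq[pp["start_b"] : pp["start_b"] + 6] == motifs[pp["motif_b"]]
                assert pp["start_b"] - (pp["start_a"] + 6) == pp["gap"] <= 20

    def test_promoter_too_short_rejected(self, rng):
        cfg = sd.SimConfig(seed=1, n_genes=2, promoter_len=30, signal_fraction=1.0,
                           planted_pairs_per_signal_gene=2, planted_gap=10)
        with pytest.raises(ValueError, match="too short"):
            sd.simulate_promoters(cfg)

    def test_zero_signal_fraction_leaves_background_untouched(self, rng):
        cfg = sd.SimConfig(seed=1, n_genes=10, signal_fraction=0.0)
        promoters, truth = sd.simulate_promoters(cfg)
        assert truth.signal_gene_ids == []
        assert len(promoters) == 10


class TestDETables:
    def test_intersection_recovers_planted_shared_set(self, rng):
        gene_ids = [f"g{i}" for i in range(300)]
        de = sd.DEConfig(n_de_shared=50, n_de_unique_a=20, n_de_unique_b=20)
        a, b, truth = sd.simulate_de_tables(gene_ids, de, rng)
        shared = intersect_de(a, b)
        assert set(shared.index) == set(truth.shared_de)
        assert len(shared) == 50

    def test_boundary_genes_excluded_by_strict_rule(self, rng):
        gene_ids = [f"g{i}" for i in range(100)]
        de = sd.DEConfig(n_de_shared=10, n_de_unique_a=5, n_de_unique_b=5,
                         n_at_alpha=3)
        a, b, truth = sd.simulate_de_tables(gene_ids, de, rng)
        boundary = a.index[(a["padj"] == 0.05) & (b["padj"] == 0.05)]
        assert len(boundary) == 3
        assert not set(boundary) & set(intersect_de(a, b).index)

    def test_unique_genes_in_one_table_only(self, rng):
        gene_ids = [f"g{i}" for i in range(200)]
        a, b, truth = sd.simulate_de_tables(gene_ids, sd.DEConfig(), rng)
        for g in truth.unique_de_a:
            assert a.loc[g, "padj"] < 0.05 <= b.loc[g, "padj"]
        for g in truth.unique_de_b:
            assert b.loc[g, "padj"] < 0.05 <= a.loc[g, "padj"]


class TestAlignments:
    def test_ground_truth_tallies_match_counting(self, rng):
        from auxrescan.expression_counting import assign_reads

        _, genes, _ = sd.simulate_genome(sd.SimConfig(seed=13, n_genes=40))
        cfg = sd.AlignmentConfig(antisense_fraction=0.2)
        records, truth = sd.simulate_alignments(genes, cfg, rng)
        counts, stats = assign_reads(records, genes, orientation="forward")
        for g in genes:
            assert counts[g.gene_id].sense_count == \
                truth.expected_counts[g.gene_id]["sense"], g.gene_id
            assert counts[g.gene_id].antisense_count == \
                truth.expected_counts[g.gene_id]["antisense"], g.gene_id
        assert stats["total_reads"] == truth.total_mapped_reads

    def test_cap_probing_reads_present(self, rng):
        _, genes, _ = sd.simulate_genome(sd.SimConfig(seed=13, n_genes=40))
        records, truth = sd.simulate_alignments(genes, sd.AlignmentConfig(), rng)
        degrees = {len(t) for t in truth.read_targets.values()}
        assert {1, 20, 21} <= degrees
        assert 0 in {len(t) for t in truth.read_targets.values()}
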