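import numpy as np
import pytest

from conftest import random_dna, toy_two_gene_record
from orgscape.genome_io import (
    Feature,
    GenomeRecord,
    partition_genome,
    read_annotation,
    read_genome,
    spliced_cds,
)


class TestReadGenome:
    def test_fasta_single_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nACGT\n")
        rec = read_genome(p)
        assert rec.seq == "ACGT" and rec.features == [] and rec.topology == "linear"

    def test_genbank_join_becomes_half_open_segments(self, toy_genbank):
        rec = read_genome(toy_genbank, "genbank")
        assert rec.topology == "circular"
        cds = rec.feature_by_gene("gA")
        assert [(a, b) for a, b, _ in cds.segments] == [(0, 6), (9, 15)]
        assert cds.spliced_length == 12

    def test_unknown_residue_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">x\nACGU\n")
        with pytest.raises(ValueError, match="U"):
            read_genome(p)

    def test_topology_override(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">x\nACGTACGT\n")
        assert read_genome(p, topology_override="circular").topology == "circular"


class TestReadAnnotation:
    def test_intron_synthesized_between_exons(self, toy_gff):
        feats = read_annotation(toy_gff)
        kinds = {(f.gene_name, f.kind) for f in feats}
        assert ("gA", "CDS") in kinds and ("gA", "intron") in kinds and ("tX", "tRNA") in kinds
        intron = next(f for f in feats if f.kind == "intron")
        assert intron.segments == [(90, 150, 1)]

    def test_orphan_child_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nc\tt\tCDS\t1\t9\t.\t+\t0\tID=x;Parent=ghost\n")
        with pytest.raises(ValueError, match="parent"):
            read_annotation(p)

    def test_mixed_strand_gene_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tt\tgene\t1\t60\t.\t+\t.\tID=g\n"
            "c\tt\tCDS\t1\t30\t.\t+\t0\tID=g.1;Parent=g\n"
            "c\tt\tCDS\t31\t60\t.\t-\t0\tID=g.2;Parent=g\n"
        )
        with pytest.raises(ValueError, match="strand"):
            read_annotation(p)

    def test_origin_spanning_gene_reconstructed(self, tmp_path):
        p = tmp_path / "wrap.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tt\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "c\tt\tCDS\t91\t100\t.\t+\t0\tID=g.1;Parent=g\n"
            "c\tt\tCDS\t1\t11\t.\t+\t0\tID=g.2;Parent=g\n"
        )
        feats = read_annotation(p, genome_length=100)
        cds = [f for f in feats if f.kind == "CDS"]
        assert len(cds) == 1
        assert [(a, b) for a, b, _ in cds[0].segments] == [(90, 100), (0, 11)]
        assert not any(f.kind == "intron" for f in feats)


class TestPartition:
    def test_featureless_genome_is_all_intergenic(self):
        rec = GenomeRecord("x", "A" * 1000, "linear")
        pm = partition_genome(rec)
        assert pm.fractions["intergenic"] == 1.0
        assert pm.intergenic_intervals == [(0, 1000)]

    def test_circular_toy_counts_and_single_interval(self):
        rec = toy_two_gene_record()
        pm = partition_genome(rec)
        assert pm.coding_dna_bp == 40
        # brute-force per-base check
        expect = np.zeros(100, dtype=int)
        expect[10:40] = 3
        expect[60:70] = 2
        assert (pm.labels == expect).all()
        # circular: the runs (70..100) and (0..10) merge, plus (40..60)
        assert sorted(length for _, length in pm.intergenic_intervals) == [20, 40]

    def test_precedence_intronic_orf_stays_intron(self):
        rec = GenomeRecord(
            "x",
            "A" * 100,
            "linear",
            [
                Feature("g", "CDS", [(0, 30, 1), (60, 90, 1)]),
                Feature("g", "intron", [(30, 60, 1)]),
                Feature("orf1", "intronic_ORF", [(40, 50, 1)]),
            ],
        )
        pm = partition_genome(rec)
        assert pm.totals == {"intergenic": 10, "intron": 30, "structural_RNA": 0, "exon": 60}

    def test_labels_sum_and_permutation_invariance(self, rng):
        for _ in range(10):
            n = int(rng.integers(50, 400))
            feats = []
            for k in range(int(rng.integers(0, 6))):
                a = int(rng.integers(0, n - 10))
                b = a + int(rng.integers(3, min(40, n - a)))
                kind = ["CDS", "intron", "tRNA", "rRNA", "intronic_ORF"][int(rng.integers(5))]
                feats.append(Feature(f"f{k}", kind, [(a, b, 1)]))
            rec = GenomeRecord("r", random_dna(rng, n), "linear", feats)
            pm = partition_genome(rec)
            assert sum(pm.totals.values()) == n
            shuffled = list(feats)
            rng.shuffle(shuffled)
            pm2 = partition_genome(GenomeRecord("r", rec.seq, "linear", shuffled))
            assert (pm.labels == pm2.labels).all()


class TestSplicedCds:
    def test_plus_strand_single_exon(self):
        rec = GenomeRecord("x", "ATGAAATAG", "linear", [Feature("g", "CDS", [(0, 9, 1)])])
        assert spliced_cds(rec, "g") == "ATGAAATAG"

    def test_minus_strand_is_reverse_complemented(self):
        rec = GenomeRecord("x", "CTACAT", "linear", [Feature("g", "CDS", [(0, 6, -1)])])
        assert spliced_cds(rec, "g") == "ATGTAG"

    def test_two_exon_concatenation(self, toy_genbank):
        rec = read_genome(toy_genbank, "genbank")
        assert spliced_cds(rec, "gA") == rec.seq[0:6] + rec.seq[9:15]

    def test_unknown_gene_lists_alternatives(self):
        rec = toy_two_gene_record()
        with pytest.raises(KeyError, match="g1"):
            spliced_cds(rec, "nope")

    def test_mirror_symmetry_under_genome_revcomp(self, rng):
        from orgscape._seq import revcomp

        n = 200
        seq = random_dna(rng, n)
        segs = [(20, 50, 1), (80, 110, 1)]
        rec = GenomeRecord("x", seq, "linear", [Feature("g", "CDS", segs)])
        mirrored = [(n - b, n - a, -1) for a, b, _ in segs]
        rec2 = GenomeRecord("x", revcomp(seq), "linear", [Feature("g", "CDS", mirrored)])
        assert spliced_cds(rec, "g") == spliced_cds(rec2, "g")
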