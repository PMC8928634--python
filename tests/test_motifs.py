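import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_motif_hits, random_dna
from orgscape._seq import revcomp
from orgscape.genome_io import GenomeRecord, partition_genome
from orgscape.motifs import MotifHit, census, compile_pattern, detect_arrays, find_hits
from orgscape.synthetic import GeneModel, GenomeSpec, PlantDirective, build_genome


class TestCompilePattern:
    def test_bracket_alternatives(self):
        p = compile_pattern("GCTGAC[AT]T")
        assert len(p) == 8 and p.n_expansions == 2
        assert sorted(p.expansions()) == ["GCTGACAT", "GCTGACTT"]

    def test_spaces_and_pipes_are_cosmetic(self):
        assert len(compile_pattern("AAGCCAGC NNN GCTGACTT")) == 19
        assert compile_pattern("AAGCCAGC|NNN|GCTGACTT").pattern == "AAGCCAGCNNNGCTGACTT"

    def test_reverse_complement_pattern(self):
        p = compile_pattern("CAAACCAGTNNACTGGTTAG")
        assert p.reverse_complement().pattern == "CTAACCAGTNNACTGGTTTG"

    def test_self_revcomp_detection(self):
        assert compile_pattern("AAGTCAGCNNNGCTGACTT").self_revcomp
        assert not compile_pattern("AAGCCAGCNNNGCTGACTT").self_revcomp

    @pytest.mark.parametrize("bad", ["AC[GT", "AC]G", "ACX", "A[]C", ""])
    def test_malformed_patterns_rejected(self, bad):
        with pytest.raises(ValueError):
            compile_pattern(bad)


class TestFindHits:
    def test_overlapping_matches_all_reported(self):
        rec = GenomeRecord("x", "AAAA", "linear")
        hits = find_hits(compile_pattern("AAA", "m"), rec)
        direct = [(h.start) for h in hits if h.orientation == "direct"]
        assert direct == [0, 1]

    def test_circular_wrap_match(self):
        rec = GenomeRecord("x", "CGTACGTAAC", "circular")
        # 'ACCG' spans the origin (positions 8,9 then 0,1)
        hits = find_hits(compile_pattern("ACCG", "m"), rec)
        assert any(h.start == 8 and h.orientation == "direct" for h in hits)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_windows(self, seed):
        r = np.random.default_rng(seed)
        seq = random_dna(r, int(r.integers(30, 400)))
        # random degenerate pattern over {literal, N, R/Y, bracket}
        length = int(r.integers(4, 9))
        parts = []
        for _ in range(length):
            kind = r.integers(4)
            if kind == 0:
                parts.append("N")
            elif kind == 1:
                parts.append("RYSWKM"[r.integers(6)])
            elif kind == 2:
                parts.append("[" + "".join(sorted({"ACGT"[i] for i in r.integers(0, 4, 2)})) + "]")
            else:
                parts.append("ACGT"[r.integers(4)])
        pat = compile_pattern("".join(parts), "m")
        rec = GenomeRecord("x", seq, "linear")
        got = {(h.start, h.orientation) for h in find_hits(pat, rec)}
        assert got == brute_motif_hits(pat.sets, seq)

    def test_exonic_hit_carries_gene_frame_and_coding_orientation(self):
        spec = GenomeSpec(
            length=30_000, seed=5,
            gene_models=[GeneModel("gneg", [600], strand=-1)],
            repeat_plan=[PlantDirective(
                "AAAGATAAGTCAGCAGAGCTGAC[AT]TCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT",
                "exonic_insertion", 2, name="c", target="gneg")],
        )
        rec, man = build_genome(spec)
        pat = compile_pattern("AAAGATAAGTCAGCAGAGCTGAC[AT]TCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT", "c")
        hits = [h for h in find_hits(pat, rec) if h.partition == "exon"]
        assert len(hits) == 2
        for h in hits:
            assert h.gene == "gneg"
            assert h.orientation == "direct"  # relative to the coding strand
            assert h.frame_offset == 0


class TestCensus:
    def test_nested_child_counts_propagate_to_ancestor(self, rng):
        seq = random_dna(rng, 2000)
        seq = seq[:500] + "A" + "AAGTCAGC" + "ACG" + "GCTGACTT" + "A" + seq[500:]
        rec = GenomeRecord("x", seq, "linear")
        root = compile_pattern("AAG[CT]CAGCNNNGCTGACTT", "root")
        child = compile_pattern("AAGTCAGCNNNGCTGACTT", "child", variant_parent="root")
        counts = census([root, child], rec)
        df = counts.by_partition.set_index("motif")
        assert df.loc["child", "total"] <= df.loc["root", "total"]
        assert df.loc["root", "total"] >= 1

    def test_self_revcomp_motif_single_orientation(self, rng):
        seq = random_dna(rng, 1000) + "AAGTCAGCACGGCTGACTT" + random_dna(rng, 1000)
        rec = GenomeRecord("x", seq, "linear")
        counts = census([compile_pattern("AAGTCAGCNNNGCTGACTT", "v1")], rec)
        assert counts.self_revcomp["v1"]
        row = counts.by_partition.iloc[0]
        assert row["intergenic_revcomp"] == 0 and row["intergenic_direct"] >= 1

    def test_orientation_totals_swap_under_genome_revcomp(self, rng):
        seq = random_dna(rng, 3000)
        seq = seq[:100] + "TGGTTAGTAACTAAACTTCCAAACCAGTAAAC" + seq[100:]
        pat = compile_pattern("TGGTTAGTAACTAAACTTCCAAACCAGTAAAC", "m")
        fwd = census([pat], GenomeRecord("x", seq, "linear")).by_partition.iloc[0]
        rev = census([pat], GenomeRecord("x", revcomp(seq), "linear")).by_partition.iloc[0]
        assert fwd["intergenic_direct"] == rev["intergenic_revcomp"]
        assert fwd["intergenic_revcomp"] == rev["intergenic_direct"]


class TestDetectArrays:
    def _mk(self, starts, motif="a", length=10):
        return [MotifHit(motif, s, length, "direct", "intergenic") for s in starts]

    def test_far_apart_hits_form_no_array(self):
        hits = self._mk(range(0, 50_000, 10_000))
        assert detect_arrays(hits, min_copies=3, max_gap=100) == []

    def test_interleaved_pair_classified(self):
        hits = []
        pos = 0
        for i in range(14):
            hits.append(MotifHit("a" if i % 2 == 0 else "b", pos, 10, "direct", "intergenic"))
            pos += 12
        arrays = detect_arrays(hits, 3, 20)
        assert len(arrays) == 1
        assert arrays[0].interleaved and arrays[0].copies == {"a": 7, "b": 7}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_run_segmentation(self, seed):
        r = np.random.default_rng(seed)
        starts = np.cumsum(r.integers(10, 60, size=int(r.integers(2, 40))))
        hits = self._mk([int(s) for s in starts])
        max_gap = int(r.integers(5, 50))
        min_copies = int(r.integers(2, 5))
        arrays = detect_arrays(hits, min_copies, max_gap)
        # oracle: exhaustive segmentation at gaps > max_gap
        runs, cur = [], [hits[0]]
        for h in hits[1:]:
            if h.start - cur[-1].end <= max_gap:
                cur.append(h)
            else:
                runs.append(cur)
                cur = [h]
        runs.append(cur)
        expect = [(run[0].start, run[-1].end, len(run)) for run in runs if len(run) >= min_copies]
        assert [(a.start, a.end, a.n_hits) for a in arrays] == expect
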