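import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgscape._seq import STOP_CODONS, revcomp
from orgscape.frames import (
    RARITY_LEVELS,
    SENSE_CODONS,
    codon_usage,
    gc_rich_aa_fraction,
    phase_bias_report,
    rarity_categories,
    six_frame_profile,
)
from orgscape.motifs import MotifHit, compile_pattern

COMPOSITE60 = "AAAGATAAGTCAGCAGAGCTGAC[AT]TCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT"


class TestCodonUsage:
    def test_simple_counts(self):
        u = codon_usage(["ATGAAATAG"])
        assert u.counts == {"ATG": 1, "AAA": 1, "TAG": 1} and u.total_codons == 3

    def test_order_invariance(self):
        a = codon_usage(["ATGAAATAG", "ATGCCCTAA"])
        b = codon_usage(["ATGCCCTAA", "ATGAAATAG"])
        assert a.counts == b.counts

    def test_trailing_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="partial"):
            u = codon_usage(["ATGAA"])
        assert u.total_codons == 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            codon_usage([])


def _oracle_categories(counts: dict, thresholds=(2, 4, 10, 20)):
    """Independent cumulative-sum construction of the rarity categories."""
    total = sum(counts.values())
    observed = sorted(
        (c for c in counts if c in SENSE_CODONS and counts[c] > 0),
        key=lambda c: (counts[c] / total, c),
    )
    out = {}
    for thr in thresholds:
        cum, members = 0.0, []
        for c in observed:
            if (cum + counts[c] / total) * 100 < thr:
                cum += counts[c] / total
                members.append(c)
            else:
                break
        out[thr] = set(members)
    return out


class TestRarityCategories:
    def test_uniform_usage_singleton_rare2(self):
        u = codon_usage([c for c in SENSE_CODONS])
        rt = rarity_categories(u)
        assert rt.members("rare2") == {"AAA"}  # lexicographic tie-winner
        assert rt.members("rare4") == {"AAA", "AAC"}

    def test_three_codon_example(self):
        u = codon_usage(["AAA"] * 97 + ["CCC"] * 2 + ["GGG"])
        rt = rarity_categories(u)
        assert rt.members("rare2") == {"GGG"}
        assert rt.members("rare4") == {"GGG", "CCC"}

    def test_common50_is_minimal_majority_suffix(self):
        u = codon_usage(["AAA"] * 60 + ["CCC"] * 30 + ["GGG"] * 10)
        rt = rarity_categories(u)
        assert rt.members("common50") == {"AAA"}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_cumulative_sum_oracle(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(3, 40))
        codons = list(r.choice(SENSE_CODONS, size=k, replace=False))
        counts = {c: int(r.integers(1, 500)) for c in codons}
        from orgscape.frames import CodonUsageTable

        usage = CodonUsageTable(counts, sum(counts.values()))
        rt = rarity_categories(usage)
        oracle = _oracle_categories(counts)
        for thr, level in zip((2, 4, 10, 20), RARITY_LEVELS):
            assert rt.members(level) == oracle[thr], f"threshold {thr}%"
        # nesting
        assert rt.members("rare2") <= rt.members("rare4") <= rt.members("rare10") <= rt.members("rare20")
        assert not (rt.members("rare20") & set(STOP_CODONS))


class TestSixFrameProfile:
    @pytest.fixture
    def rarity(self):
        rng = np.random.default_rng(0)
        counts = {c: int(rng.integers(1, 400)) for c in SENSE_CODONS}
        from orgscape.frames import CodonUsageTable

        return rarity_categories(CodonUsageTable(counts, sum(counts.values())))

    def test_composite60_in_frame_is_stop_free_20_residues(self, rarity):
        prof = six_frame_profile(compile_pattern(COMPOSITE60, "c60"), rarity)
        row = prof.table.loc["+0"]
        assert row["n_codons"] == 20
        assert row["stop_min"] == 0 and row["stop_max"] == 0
        assert len(prof.peptides["+0"]) == 20 and "*" not in prof.peptides["+0"]

    def test_variant8_reconstruction_translates_to_published_peptide(self, rarity):
        prof = six_frame_profile(compile_pattern("AAAGATAAGCCAGCAAATCTGACTTCA", "v8"), rarity)
        assert prof.peptides["+0"] == "KDKPANLTS"

    def test_literal_stop_codon(self, rarity):
        prof = six_frame_profile(compile_pattern("TAA", "stop"), rarity)
        assert prof.table.loc["+0", "stop_min"] == 1 and prof.table.loc["+0", "stop_max"] == 1

    def test_bounds_attained_by_exhaustive_expansion(self, rarity):
        pat = compile_pattern("AAGNCAGC[AT]T", "p")
        prof = six_frame_profile(pat, rarity)
        for frame in ("+0", "+1", "+2"):
            off = int(frame[1])
            vals = {"stop": [], "rareAA": []}
            for lvl in RARITY_LEVELS:
                vals[lvl] = []
            for exp in pat.expansions():
                codons = [exp[i : i + 3] for i in range(off, len(exp) - (len(exp) - off) % 3, 3)]
                codons = [c for c in codons if len(c) == 3]
                vals["stop"].append(sum(c in STOP_CODONS for c in codons))
                for lvl in RARITY_LEVELS:
                    vals[lvl].append(sum(c in rarity.members(lvl) for c in codons))
            assert prof.table.loc[frame, "stop_min"] == min(vals["stop"])
            assert prof.table.loc[frame, "stop_max"] == max(vals["stop"])
            for lvl in RARITY_LEVELS:
                assert prof.table.loc[frame, f"{lvl}_min"] == min(vals[lvl])
                assert prof.table.loc[frame, f"{lvl}_max"] == max(vals[lvl])

    def test_plus0_equals_minus0_of_revcomp(self, rarity):
        pat = compile_pattern("AAGCCAGCNNNGCTGACTT", "p")
        rc = pat.reverse_complement()
        a = six_frame_profile(pat, rarity).table
        b = six_frame_profile(rc, rarity).table
        assert a.loc["+0"].equals(b.loc["-0"])

    def test_too_short_motif_rejected(self, rarity):
        with pytest.raises(ValueError):
            six_frame_profile(compile_pattern("AT", "x"), rarity)


class TestPhaseBias:
    def _rarity(self):
        from orgscape.frames import CodonUsageTable

        counts = {c: 10 for c in SENSE_CODONS}
        return rarity_categories(CodonUsageTable(counts, sum(counts.values())))

    def test_all_in_frame_direct_mass(self):
        hits = [
            MotifHit("m", 100 * i, 60, "direct", "exon", gene="g", frame_offset=0,
                     sequence="AAAGATAAGTCAGCAGAGCTGACATCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT")
            for i in range(5)
        ]
        rep = phase_bias_report(hits, self._rarity())
        assert rep.contingency.loc["direct", 0] == 5
        assert rep.in_frame_stop_total == 0 and rep.disrupting_hits == []

    def test_stop_containing_reading_flagged(self):
        h = MotifHit("m", 0, 9, "direct", "exon", gene="g", frame_offset=0, sequence="AAATAAAAA")
        rep = phase_bias_report([h], self._rarity())
        assert rep.in_frame_stop_total == 1 and rep.disrupting_hits == [h]

    def test_offset_reading_skips_leading_partial_codon(self):
        # offset 2: first complete host codon starts at position 1 inside the hit
        h = MotifHit("m", 0, 8, "direct", "exon", gene="g", frame_offset=2, sequence="ATAAGGGC")
        rep = phase_bias_report([h], self._rarity())
        assert rep.in_frame_stop_total == 1  # TAA at offset 1


class TestGcRichAa:
    @pytest.mark.parametrize("prot,frac", [("GARP", 1.0), ("KKKK", 0.0), ("GAKP", 0.75)])
    def test_fraction(self, prot, frac):
        assert gc_rich_aa_fraction(prot) == frac

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_rich_aa_fraction("")
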