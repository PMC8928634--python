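import numpy as np
import pytest

from orgscape._seq import revcomp
from orgscape.genome_io import Feature, GenomeRecord

TOY_GENBANK = """\
LOCUS       toy                       30 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  toy record.
ACCESSION   toy
FEATURES             Location/Qualifiers
     CDS             join(1..6,10..15)
                     /gene="gA"
     tRNA            20..25
                     /gene="tX"
ORIGIN
        1 atgaaacccg gtaaacccgg gtttaaacgc
//
"""

TOY_GFF = """\
##gff-version 3
toy\ttest\tgene\t1\t240\t.\t+\t.\tID=gA;Name=gA
toy\ttest\tCDS\t1\t90\t.\t+\t0\tID=gA.1;Parent=gA
toy\ttest\tCDS\t151\t240\t.\t+\t0\tID=gA.2;Parent=gA
toy\ttest\ttRNA\t250\t260\t.\t-\t.\tID=tX;Name=tX
"""


@pytest.fixture
def toy_genbank(tmp_path):
    p = tmp_path / "toy.gb"
    p.write_text(TOY_GENBANK)
    return p


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF)
    return p


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def toy_two_gene_record(seq_len: int = 100) -> GenomeRecord:
    """100 bp circular toy: one 30 bp CDS, one 10 bp tRNA, rest intergenic."""
    rng = np.random.default_rng(3)
    seq = random_dna(rng, seq_len)
    seq = seq[:10] + "ATG" + seq[13:37] + "TAA" + seq[40:]
    features = [
        Feature("g1", "CDS", [(10, 40, 1)]),
        Feature("t1", "tRNA", [(60, 70, 1)]),
    ]
    return GenomeRecord("toy2", seq, "circular", features)


def brute_palindromes(seq: str, cfg) -> set:
    """Independent enumeration oracle for the palindrome scanner: test every
    (center, spacer, arm) triple directly and apply the maximality rule."""
    n = len(seq)
    out = set()
    for s in range(cfg.spacer_min, cfg.spacer_max + 1):
        for p in range(n + 1):
            arms = {}
            for a in range(1, cfg.arm_max + 1):
                if p - a < 0 or p + s + a > n:
                    break
                left = seq[p - a : p]
                right = seq[p + s : p + s + a]
                arms[a] = sum(x != y for x, y in zip(left, revcomp(right)))
            for a, mm in arms.items():
                if a < cfg.arm_min or mm > cfg.max_mismatch:
                    continue
                if any(a2 > a and mm2 <= mm for a2, mm2 in arms.items() if mm2 <= cfg.max_mismatch):
                    continue
                out.add((p - a, a, s, mm))
    return out


def brute_motif_hits(pattern_sets, seq: str) -> set:
    """Window-by-window degenerate matching oracle, both orientations."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = len(pattern_sets)
    rc_sets = [frozenset(comp[b] for b in s) for s in reversed(pattern_sets)]
    self_rc = list(pattern_sets) == rc_sets
    out = set()
    for i in range(len(seq) - L + 1):
        w = seq[i : i + L]
        if all(c in s for c, s in zip(w, pattern_sets)):
            out.add((i, "direct"))
        if not self_rc and all(c in s for c, s in zip(w, rc_sets)):
            out.add((i, "revcomp"))
    return out
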