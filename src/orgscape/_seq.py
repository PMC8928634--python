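"""Low-level sequence helpers shared across modules.

Internal convention: DNA strings are uppercase over {A,C,G,T,N}; numeric
encoding maps A,C,G,T -> 0..3 and N -> 100 (a sentinel that can never
satisfy the complement identity code_a + code_b == 3, so N never pairs).
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide codes -> the set of literal bases they stand for.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_CODE = np.full(256, 100, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

# standard genetic code (the one used by chlorophyte organellar genes)
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TO_AA = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0,C=1,G=2,T=3,N=100)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate(cds: str) -> str:
    """Translate complete codons; '*' marks stops, 'X' any codon with N."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aas.append(CODON_TO_AA.get(cds[i : i + 3], "X"))
    return "".join(aas)


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T (N excluded from numerator and denominator)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def validate_dna(seq: str, context: str = "sequence") -> str:
    """Uppercase and reject residues outside {A,C,G,T,N}."""
    seq = seq.upper()
    bad = sorted(set(seq) - DNA_ALPHABET)
    if bad:
        raise ValueError(f"{context}: unknown residues {''.join(bad)!r} (only A,C,G,T,N allowed)")
    return seq
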