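"""Imperfect-palindrome (inverted repeat) discovery and ranking.

An imperfect palindrome (IP) is written L|S|R: two arms L and R whose
reverse complements match within a mismatch budget, separated by a short
spacer S (the presumed loop of a cruciform/hairpin). The scanner reports
maximal hits per center: at a fixed (spacer position, spacer length), a
shorter arm is suppressed whenever a longer arm with at most the same
number of mismatches exists. A site and its reverse complement are the
same physical palindrome and are reported once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .genome_io import EXON, GenomeRecord, PartitionMap


@dataclass(frozen=True)
class PalindromeHit:
    start: int  # genome coordinate of the left arm's first base
    arm_len: int
    spacer_len: int
    mismatches: int
    sequence: str  # left arm + spacer + right arm as read on the reference strand

    @property
    def end(self) -> int:
        return self.start + 2 * self.arm_len + self.spacer_len

    def form(self, mask_spacer: bool = True) -> str:
        """``L|S|R`` notation; the spacer is masked as an N-run by default."""
        a, s = self.arm_len, self.spacer_len
        spacer = "N" * s if mask_spacer else self.sequence[a : a + s]
        return f"{self.sequence[:a]}|{spacer}|{self.sequence[a + s :]}"

    def canonical_form(self, mask_spacer: bool = True) -> str:
        """Strand-invariant form: lexicographic min of the form and its revcomp."""
        f = self.form(mask_spacer)
        rc = _revcomp_form(f)
        return min(f, rc)


def _revcomp_form(form: str) -> str:
    left, spacer, right = form.split("|")
    return f"{revcomp(right)}|{revcomp(spacer)}|{revcomp(left)}"


@dataclass
class ScanConfig:
    arm_min: int = 8
    arm_max: int = 100
    spacer_min: int = 0
    spacer_max: int = 10
    max_mismatch: int = 1
    circular: bool = False

    def __post_init__(self):
        if self.arm_min > self.arm_max or self.spacer_min > self.spacer_max:
            raise ValueError("min must not exceed max in arm/spacer ranges")
        if self.arm_min < 1 or self.spacer_min < 0 or self.max_mismatch < 0:
            raise ValueError("invalid scan configuration")


def classify_motif(motif: str) -> tuple[int, int, int]:
    """Parse ``L|S|R`` notation into (arm_len, spacer_len, mismatches).

    Mismatches = Hamming distance between L and reverse-complement(R); the
    spacer (explicit bases, an N-run, or '-'/'‒' for none) is ignored.
    """
    parts = motif.replace("‒", "-").split("|")
    if len(parts) != 3:
        raise ValueError(f"expected L|S|R notation, got {motif!r}")
    left, spacer, right = parts
    if spacer == "-":
        spacer = ""
    if len(left) != len(right):
        raise ValueError(f"unequal arms in {motif!r}: {len(left)} vs {len(right)} bp")
    rc = revcomp(right)
    mism = sum(a != b for a, b in zip(left, rc))
    return len(left), len(spacer), mism


def scan_palindromes(rec: GenomeRecord | str, cfg: ScanConfig | None = None) -> list[PalindromeHit]:
    """Find every maximal imperfect palindrome satisfying ``cfg``.

    Circular genomes are scanned across the origin; hit coordinates are
    reported modulo the genome length with the left arm's start in [0, L).
    """
    cfg = cfg or ScanConfig()
    seq = rec.seq if isinstance(rec, GenomeRecord) else rec
    circular = cfg.circular or (isinstance(rec, GenomeRecord) and rec.topology == "circular")
    n = len(seq)
    if n < 2 * cfg.arm_min + cfg.spacer_min:
        if 2 * cfg.arm_min > n and not circular:
            raise ValueError(f"arm_min {cfg.arm_min} too large for genome of length {n}")
        return []

    ext = 0
    if circular:
        ext = min(n - 1, 2 * cfg.arm_max + cfg.spacer_max - 1)
    codes = encode(seq + seq[:ext])
    m = len(codes)

    hits: list[PalindromeHit] = []
    budget = cfg.max_mismatch
    for s in range(cfg.spacer_min, cfg.spacer_max + 1):
        amax = min(cfg.arm_max, (m - s) // 2)
        if amax < cfg.arm_min:
            continue
        # mm[j, p] = True if arm pair j at center p mismatches (or is out of range);
        # center p = position just right of the left arm (= spacer start)
        mism = np.ones((amax, m + 1), dtype=bool)
        for j in range(amax):
            lo, hi = j + 1, m - s - j  # valid p range for pair j
            if lo >= hi:
                break
            left = codes[lo - 1 - j : hi - 1 - j]
            right = codes[lo + s + j : hi + s + j]
            mism[j, lo:hi] = (left.astype(np.int16) + right) != 3
        cum = np.cumsum(mism, axis=0, dtype=np.int16)
        # arm_m[p] = maximal arm with <= m_ mismatches
        arms_by_level = []
        for m_ in range(budget + 1):
            arm = np.minimum((cum <= m_).sum(axis=0), amax)
            arms_by_level.append(arm)
        arms_stack = np.stack(arms_by_level)  # (budget+1, m+1)
        candidate = (arms_stack >= cfg.arm_min).any(axis=0)
        for p in np.flatnonzero(candidate):
            reported: set[int] = set()
            for m_ in range(budget + 1):
                a = int(arms_stack[m_, p])
                if a < cfg.arm_min or a in reported:
                    continue
                # suppressed if a longer arm exists with <= the same mismatches
                mm_here = int(cum[a - 1, p])
                longer = [int(arms_stack[k, p]) for k in range(budget + 1) if int(arms_stack[k, p]) > a]
                if any(int(cum[la - 1, p]) <= mm_here for la in longer):
                    continue
                reported.add(a)
                start = p - a
                if circular and start >= n:
                    continue  # duplicate of a hit already reported in [0, n)
                if not circular and (start < 0 or p + s + a > n):
                    continue
                end = p + s + a
                if end <= m:
                    hit_seq = _slice(seq, start, end, n, circular)
                    hits.append(PalindromeHit(start % n, a, s, mm_here, hit_seq))
        del mism, cum, arms_stack
    hits.sort(key=lambda h: (h.start, h.spacer_len, h.arm_len))
    return hits


def _slice(seq: str, start: int, end: int, n: int, circular: bool) -> str:
    if start >= 0 and end <= n:
        return seq[start:end]
    if not circular:
        raise AssertionError("out-of-range slice on a linear genome")
    doubled = seq + seq
    return doubled[start % n : start % n + (end - start)]


def rank_ips(
    hits: list[PalindromeHit],
    canonicalization: str = "spacer_masked",
    partition: PartitionMap | None = None,
) -> pd.DataFrame:
    """Abundance table of palindrome forms, most copies first.

    Groups hits by their strand-invariant canonical form (spacer masked as
    an N-run unless ``canonicalization='exact'``); ties are broken by form
    lexicographically. With a partition map, exon-resident counts are
    reported alongside, keeping forms with zero exon occurrences visible.
    """
    if canonicalization not in ("exact", "spacer_masked"):
        raise ValueError(f"unknown canonicalization {canonicalization!r}")
    mask = canonicalization == "spacer_masked"
    rows: dict[str, dict] = {}
    for h in hits:
        key = h.canonical_form(mask_spacer=mask)
        row = rows.setdefault(
            key, {"form": key, "arm_len": h.arm_len, "spacer_len": h.spacer_len,
                  "mismatches": h.mismatches, "count": 0, "exon_count": 0}
        )
        row["count"] += 1
        if partition is not None and partition.labels[h.start] == EXON:
            row["exon_count"] += 1
    table = pd.DataFrame(rows.values(), columns=["form", "arm_len", "spacer_len", "mismatches", "count", "exon_count"])
    if len(table):
        table = table.sort_values(["count", "form"], ascending=[False, True], kind="stable").reset_index(drop=True)
    if partition is None:
        table = table.drop(columns=["exon_count"])
    return table


__all__ = ["PalindromeHit", "ScanConfig", "classify_motif", "scan_palindromes", "rank_ips"]
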