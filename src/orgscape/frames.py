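"""Coding-sequence impact of repeat insertions.

Codon usage over a CDS set, cumulative rarity categories (the least-used
codons jointly staying under 2/4/10/20% of all codons, plus the most-used
codons jointly exceeding 50%), rare amino acids, six-frame translation of
degenerate motifs with min/max stop and rare-codon counts over all
expansions, and a descriptive orientation-by-phase bias report for exonic
repeat copies.

Frames are named +0/+1/+2 on the given strand and -0/-1/-2 on the reverse
complement; the offset counts from the motif's first base and only complete
in-motif codons are scored (boundary codons depend on genomic context,
which the phase-bias report handles per hit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import pandas as pd

from ._seq import CODON_TO_AA, STOP_CODONS, translate
from .motifs import MotifHit, MotifPattern

RARITY_LEVELS = ("rare2", "rare4", "rare10", "rare20")
ALL_CODONS = sorted(CODON_TO_AA)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
GARP = frozenset("GARP")


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    total_codons: int

    @property
    def frequencies(self) -> dict[str, float]:
        return {c: self.counts.get(c, 0) / self.total_codons for c in ALL_CODONS}


@dataclass
class CodonRarityTable:
    """Nested rarity categories over sense codons, plus the rare amino acids.

    ``category[c]`` is the tightest category containing codon c:
    rare2 ⊆ rare4 ⊆ rare10 ⊆ rare20; codons above the 20% mark fall in
    'mid' unless they belong to the most-used set jointly exceeding 50%
    ('common50'). Stop codons carry no category.
    """

    category: dict[str, str]
    rare_amino_acids: frozenset

    def members(self, level: str) -> frozenset:
        """Cumulative membership: members('rare10') includes rare2 and rare4."""
        if level in RARITY_LEVELS:
            upto = RARITY_LEVELS.index(level)
            return frozenset(c for c, cat in self.category.items() if cat in RARITY_LEVELS[: upto + 1])
        return frozenset(c for c, cat in self.category.items() if cat == level)


def codon_usage(cds_set: list[str]) -> CodonUsageTable:
    """Count codons over a set of spliced CDS strings.

    Trailing partial codons are dropped with a warning; codon order within
    and between CDSs does not affect the table.
    """
    if not cds_set:
        raise ValueError("empty CDS set")
    counts: dict[str, int] = {}
    for cds in cds_set:
        if len(cds) % 3 != 0:
            warnings.warn(f"CDS length {len(cds)} not divisible by 3; trailing partial codon dropped", stacklevel=2)
        for i in range(0, len(cds) - len(cds) % 3, 3):
            codon = cds[i : i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    total = sum(counts.values())
    return CodonUsageTable(counts, total)


def rarity_categories(
    usage: CodonUsageTable,
    thresholds: tuple = (2, 4, 10, 20),
    common_threshold: float = 50,
    n_rare_aa: int = 2,
) -> CodonRarityTable:
    """Derive nested rarity categories from a codon-usage table.

    Sense codons are sorted by ascending frequency (ties broken
    lexicographically); rareX is the maximal prefix of that ordering whose
    cumulative frequency stays strictly below X% of all codons, and
    common50 the minimal suffix whose cumulative frequency exceeds 50%.
    Rare amino acids default to the two least-used ones.
    """
    if usage.total_codons <= 0:
        raise ValueError("usage table is empty")
    freq = usage.frequencies
    # rank only codons actually observed in the CDS set: an unobserved codon
    # has no usage evidence and would otherwise flood the rare prefix
    observed = [c for c in SENSE_CODONS if usage.counts.get(c, 0) > 0]
    order = sorted(observed, key=lambda c: (freq[c], c))
    category = {c: ("mid" if c in observed else "unobserved") for c in SENSE_CODONS}

    cum = 0.0
    idx = 0
    cuts = []
    for thr in thresholds:
        while idx < len(order) and (cum + freq[order[idx]]) * 100 < thr:
            cum += freq[order[idx]]
            idx += 1
        cuts.append(idx)
    for level, (lo, hi) in zip(RARITY_LEVELS, zip([0] + cuts, cuts)):
        for c in order[lo:hi]:
            category[c] = level

    cum = 0.0
    k = len(order)
    while k > 0 and cum * 100 <= common_threshold:
        k -= 1
        cum += freq[order[k]]
    for c in order[k:]:
        if category[c] == "mid":
            category[c] = "common50"

    aa_freq: dict[str, float] = {}
    for c in SENSE_CODONS:
        aa = CODON_TO_AA[c]
        aa_freq[aa] = aa_freq.get(aa, 0.0) + freq[c]
    rare_aa = frozenset(sorted(aa_freq, key=lambda a: (aa_freq[a], a))[:n_rare_aa])
    return CodonRarityTable(category, rare_aa)


@dataclass
class FrameProfile:
    """Per-frame (min, max) stop / rare-codon / rare-AA counts for a motif."""

    table: pd.DataFrame  # index: frame; columns: n_codons, stop_min/max, <level>_min/max, rareAA_min/max
    peptides: dict[str, str]  # canonical (lexicographically first) expansion's peptide per frame
    unrealized: dict[str, list[str]]  # per frame: categories whose max is never seen in observed hits


FRAMES = ("+0", "+1", "+2", "-0", "-1", "-2")


def _frame_codon_sets(motif: MotifPattern, frame: str):
    sets = motif.sets if frame[0] == "+" else motif.reverse_complement().sets
    off = int(frame[1])
    usable = len(sets) - off
    out = []
    for i in range(off, off + usable - usable % 3, 3):
        out.append(sets[i : i + 3])
    return out


def six_frame_profile(
    motif: MotifPattern,
    rarity: CodonRarityTable,
    observed_sequences: list[str] | None = None,
) -> FrameProfile:
    """Translate a degenerate motif in all six reading frames.

    For each frame, the complete in-motif codons are enumerated over every
    degenerate expansion; stop counts, per-category rare-codon counts and
    rare-amino-acid counts are reported as (min, max) over expansions.
    Degenerate positions are independent across codons, so the bounds are
    sums of per-codon bounds and both are attained by actual expansions.
    With ``observed_sequences`` (actual genomic copies of the motif),
    categories whose theoretical maximum is never realized are flagged.
    """
    if len(motif) < 3:
        raise ValueError("motif shorter than one codon")
    cumulative_members = {lvl: rarity.members(lvl) for lvl in RARITY_LEVELS}
    rows = []
    peptides = {}
    unrealized: dict[str, list[str]] = {}
    for frame in FRAMES:
        codon_sets = _frame_codon_sets(motif, frame)
        agg = {"stop": [0, 0], "rareAA": [0, 0]}
        for lvl in RARITY_LEVELS:
            agg[lvl] = [0, 0]
        canonical = []
        for cs in codon_sets:
            triplets = ["".join(t) for t in product(*(sorted(s) for s in cs))]
            canonical.append(triplets[0])
            for key, pred in _codon_predicates(cumulative_members, rarity).items():
                vals = [pred(t) for t in triplets]
                agg[key][0] += min(vals)
                agg[key][1] += max(vals)
        row = {"frame": frame, "n_codons": len(codon_sets)}
        for key, (lo, hi) in agg.items():
            row[f"{key}_min"], row[f"{key}_max"] = lo, hi
        rows.append(row)
        peptides[frame] = translate("".join(canonical))

        if observed_sequences:
            obs_max = {k: 0 for k in agg}
            for seq in observed_sequences:
                obs = seq if frame[0] == "+" else _rc(seq)
                off = int(frame[1])
                codons = [obs[i : i + 3] for i in range(off, len(obs) - (len(obs) - off) % 3, 3)]
                for key, pred in _codon_predicates(cumulative_members, rarity).items():
                    obs_max[key] = max(obs_max[key], sum(pred(c) for c in codons if len(c) == 3))
            unrealized[frame] = [k for k in agg if agg[k][1] > 0 and obs_max[k] < agg[k][1]]
    table = pd.DataFrame(rows).set_index("frame")
    return FrameProfile(table, peptides, unrealized)


def _rc(seq: str) -> str:
    from ._seq import revcomp

    return revcomp(seq)


def _codon_predicates(cumulative_members, rarity):
    preds = {"stop": lambda t: t in STOP_CODONS}
    for lvl, members in cumulative_members.items():
        preds[lvl] = lambda t, m=members: t in m
    preds["rareAA"] = lambda t: CODON_TO_AA.get(t, "X") in rarity.rare_amino_acids
    return preds


@dataclass
class PhaseBiasReport:
    contingency: pd.DataFrame  # orientation x frame_offset counts
    fractions: pd.DataFrame
    disrupting_hits: list[MotifHit]  # hits whose in-frame reading contains a stop
    in_frame_stop_total: int
    rare_codon_total: dict[str, int]  # per cumulative rarity level, over in-frame codons


def phase_bias_report(hits: list[MotifHit], rarity: CodonRarityTable) -> PhaseBiasReport:
    """Descriptive orientation-by-phase summary of exonic repeat copies.

    Cross-tabulates coding-strand orientation against frame offset, reads
    each hit's complete in-frame codons (as carried in the hit sequence)
    against the rarity table, and flags hits whose in-frame reading would
    introduce a stop codon. Counts and fractions only — no test statistic.
    """
    exonic = [h for h in hits if h.partition == "exon" and h.frame_offset is not None]
    rows = [{"orientation": h.orientation, "frame_offset": h.frame_offset} for h in exonic]
    if rows:
        df = pd.DataFrame(rows)
        contingency = pd.crosstab(df["orientation"], df["frame_offset"])
        fractions = contingency / len(df)
    else:
        contingency = pd.DataFrame()
        fractions = pd.DataFrame()

    disrupting = []
    stop_total = 0
    rare_total = {lvl: 0 for lvl in RARITY_LEVELS}
    members = {lvl: rarity.members(lvl) for lvl in RARITY_LEVELS}
    for h in exonic:
        # first complete host-frame codon inside the hit starts at (3 - offset) % 3
        lead = (3 - h.frame_offset) % 3
        codons = [h.sequence[i : i + 3] for i in range(lead, len(h.sequence) - (len(h.sequence) - lead) % 3, 3)]
        codons = [c for c in codons if len(c) == 3]
        stops = sum(c in STOP_CODONS for c in codons)
        stop_total += stops
        if stops:
            disrupting.append(h)
        for lvl in RARITY_LEVELS:
            rare_total[lvl] += sum(c in members[lvl] for c in codons)
    return PhaseBiasReport(contingency, fractions, disrupting, stop_total, rare_total)


def gc_rich_aa_fraction(protein: str) -> float:
    """Fraction of residues encoded exclusively by GC-rich codons (G, A, R, P)."""
    if not protein:
        raise ValueError("empty protein sequence")
    return sum(aa in GARP for aa in protein) / len(protein)


__all__ = [
    "CodonUsageTable",
    "CodonRarityTable",
    "FrameProfile",
    "PhaseBiasReport",
    "RARITY_LEVELS",
    "codon_usage",
    "rarity_categories",
    "six_frame_profile",
    "phase_bias_report",
    "gc_rich_aa_fraction",
]
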