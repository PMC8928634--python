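"""Genome-composition statistics, terminal-repeat circularisation, and
dotplot word matching.

The composition report mirrors the usual organellar-genome summary table:
genome size, gene counts, GC overall and by partition, coding-DNA fraction
(exons plus structural RNAs, excluding introns and intron-borne ORFs),
intergenic totals and mean interval length, and codon GC statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import gc_fraction, revcomp
from .genome_io import (
    GenomeRecord,
    PartitionMap,
    partition_genome,
    spliced_cds,
)


@dataclass
class CompositionReport:
    genome_id: str
    size_bp: int
    topology: str
    gene_counts: dict[str, int]
    gc_overall: float
    gc_coding: float
    gc_intergenic: float
    coding_bp: int
    coding_fraction: float
    intron_bp: int
    intron_fraction: float
    intergenic_bp: int
    intergenic_fraction: float
    intergenic_mean_length: float
    intergenic_n_intervals: int
    codon_gc: float | None = None  # GC over all CDS codon positions
    codon_gc3: float | None = None  # GC at third codon positions
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "genome": self.genome_id,
            "size_bp": self.size_bp,
            "topology": self.topology,
            "n_CDS": self.gene_counts.get("CDS", 0),
            "n_tRNA": self.gene_counts.get("tRNA", 0),
            "n_rRNA": self.gene_counts.get("rRNA", 0),
            "GC_overall_pct": round(100 * self.gc_overall, 2),
            "GC_coding_pct": round(100 * self.gc_coding, 2) if self.gc_coding == self.gc_coding else "",
            "GC_intergenic_pct": round(100 * self.gc_intergenic, 2) if self.gc_intergenic == self.gc_intergenic else "",
            "coding_pct": round(100 * self.coding_fraction, 2),
            "intron_pct": round(100 * self.intron_fraction, 2),
            "intergenic_pct": round(100 * self.intergenic_fraction, 2),
            "intergenic_mean_bp": round(self.intergenic_mean_length, 1),
        }
        if self.codon_gc is not None:
            row["codon_GC_pct"] = round(100 * self.codon_gc, 2)
            row["codon_GC3_pct"] = round(100 * self.codon_gc3, 2)
        return row


def composition_report(rec: GenomeRecord, partition: PartitionMap | None = None) -> CompositionReport:
    """Compute the composition summary for one genome."""
    if partition is None:
        partition = partition_genome(rec)
    n = len(rec)
    labels = partition.labels
    seq_arr = np.frombuffer(rec.seq.encode(), dtype=np.uint8)

    def gc_of(mask: np.ndarray) -> float:
        sub = seq_arr[mask]
        if len(sub) == 0:
            return float("nan")
        gc = np.count_nonzero((sub == ord("G")) | (sub == ord("C")))
        acgt = np.count_nonzero(sub != ord("N"))
        return gc / acgt if acgt else float("nan")

    totals = partition.totals
    coding_mask = (labels == 3) | (labels == 2)
    inter_mask = labels == 0

    gene_counts: dict[str, int] = {}
    for f in rec.features:
        gene_counts[f.kind] = gene_counts.get(f.kind, 0) + 1

    cds_genes = sorted({f.gene_name for f in rec.features if f.kind == "CDS"})
    codon_gc = codon_gc3 = None
    if cds_genes:
        gc_all = gc3 = len_all = len3 = 0
        for g in cds_genes:
            cds = spliced_cds(rec, g)
            cds = cds[: len(cds) - len(cds) % 3]
            gc_all += sum(cds.count(b) for b in "GC")
            len_all += len(cds)
            third = cds[2::3]
            gc3 += sum(third.count(b) for b in "GC")
            len3 += len(third)
        codon_gc = gc_all / len_all if len_all else None
        codon_gc3 = gc3 / len3 if len3 else None

    n_inter = len(partition.intergenic_intervals)
    mean_inter = (sum(l for _, l in partition.intergenic_intervals) / n_inter) if n_inter else 0.0
    return CompositionReport(
        genome_id=rec.id,
        size_bp=n,
        topology=rec.topology,
        gene_counts=gene_counts,
        gc_overall=gc_fraction(rec.seq),
        gc_coding=gc_of(coding_mask),
        gc_intergenic=gc_of(inter_mask),
        coding_bp=partition.coding_dna_bp,
        coding_fraction=partition.coding_dna_bp / n,
        intron_bp=totals["intron"],
        intron_fraction=totals["intron"] / n,
        intergenic_bp=totals["intergenic"],
        intergenic_fraction=totals["intergenic"] / n,
        intergenic_mean_length=mean_inter,
        intergenic_n_intervals=n_inter,
        codon_gc=codon_gc,
        codon_gc3=codon_gc3,
    )


def circularise(
    rec: GenomeRecord,
    max_repeat: int = 10_000,
    min_repeat: int = 30,
    identity_floor: float = 0.9,
) -> tuple[GenomeRecord, dict]:
    """Collapse near-identical terminal direct repeats of a linear record.

    The repeat length r is chosen to maximise the excess of matching bases
    between the first and last r bp over the random expectation (0.25 per
    base), which peaks at the true repeat boundary; the candidate must then
    reach ``identity_floor``. The 5' copy is retained, the 3' copy removed,
    and the topology set to circular; the genome is reported starting at
    its original position 0.
    """
    if rec.topology == "circular":
        raise ValueError("record is already circular")
    n = len(rec)
    rmax = min(max_repeat, n // 2)
    if rmax < min_repeat:
        raise ValueError("sequence too short for terminal-repeat detection")
    head = np.frombuffer(rec.seq[:rmax].encode(), dtype=np.uint8)
    tail = np.frombuffer(rec.seq[-rmax:].encode(), dtype=np.uint8)
    best_r, best_excess, best_matches = 0, -np.inf, 0
    # matches(r) compares seq[:r] with seq[n-r:]; build via per-r vector compare
    for r in range(min_repeat, rmax + 1):
        matches = int(np.count_nonzero(head[:r] == tail[rmax - r :]))
        excess = matches - 0.25 * r
        if excess > best_excess:
            best_r, best_excess, best_matches = r, excess, matches
    identity = best_matches / best_r if best_r else 0.0
    if best_r == 0 or identity < identity_floor:
        raise ValueError(
            f"no terminal repeat: best candidate {best_r} bp at identity {identity:.3f} "
            f"(floor {identity_floor})"
        )
    new = GenomeRecord(rec.id, rec.seq[: n - best_r], "circular", list(rec.features))
    info = {"repeat_length": best_r, "identity": identity, "new_length": len(new)}
    return new, info


@dataclass
class DotplotMatches:
    word: int
    self_mode: bool
    matches: list[tuple[int, int, str]]  # (x in A, y in B, 'direct'|'revcomp')


def dotplot_matches(seq_a: str, seq_b: str | None = None, word: int = 15) -> DotplotMatches:
    """Coordinates of exact shared words between two sequences.

    ``seq_b=None`` selects self mode (A against itself), whose match list
    always contains the main diagonal and is symmetric under (x, y) ->
    (y, x). Reverse-complement word matches are reported with orientation
    'revcomp'; x is the position in A, y the position in B.
    """
    if word < 4:
        raise ValueError("word size must be >= 4")
    self_mode = seq_b is None
    if self_mode:
        seq_b = seq_a
    index: dict[str, list[int]] = {}
    for i in range(len(seq_a) - word + 1):
        index.setdefault(seq_a[i : i + word], []).append(i)
    matches: list[tuple[int, int, str]] = []
    for j in range(len(seq_b) - word + 1):
        w = seq_b[j : j + word]
        for i in index.get(w, ()):
            matches.append((i, j, "direct"))
        for i in index.get(revcomp(w), ()):
            matches.append((i, j, "revcomp"))
    return DotplotMatches(word, self_mode, matches)


__all__ = ["CompositionReport", "DotplotMatches", "composition_report", "circularise", "dotplot_matches"]
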