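"""Degenerate motif patterns: compilation, genome-wide matching, censusing,
and tandem/interleaved array detection.

Patterns are fixed-length strings over IUPAC codes with optional bracketed
alternatives, e.g. ``GCTGAC[AT]T``. Spaces and '|' separators (the L|S|R
palindrome notation) are cosmetic and stripped. A pattern expands to the
Cartesian product of its per-position base sets, so reverse complementation
and self-reverse-complement detection work position-wise without
enumerating expansions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seq import IUPAC, revcomp
from .genome_io import EXON, INTRON, LABEL_NAMES, GenomeRecord, PartitionMap


def _complement_set(s: frozenset) -> frozenset:
    table = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return frozenset(table[b] for b in s)


@dataclass(frozen=True)
class MotifPattern:
    name: str
    pattern: str  # normalized text (separators stripped)
    sets: tuple[frozenset, ...]
    variant_parent: str | None = None

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def n_expansions(self) -> int:
        n = 1
        for s in self.sets:
            n *= len(s)
        return n

    def reverse_complement(self) -> "MotifPattern":
        sets = tuple(_complement_set(s) for s in reversed(self.sets))
        return replace(self, name=self.name + "_rc", pattern=_sets_to_text(sets), sets=sets)

    @property
    def self_revcomp(self) -> bool:
        return self.sets == tuple(_complement_set(s) for s in reversed(self.sets))

    def to_regex(self) -> str:
        out = []
        for s in self.sets:
            out.append(next(iter(s)) if len(s) == 1 else "[" + "".join(sorted(s)) + "]")
        return "".join(out)

    def expansions(self, limit: int = 100_000) -> list[str]:
        if self.n_expansions > limit:
            raise ValueError(f"pattern {self.name}: {self.n_expansions} expansions exceed limit {limit}")
        out = [""]
        for s in self.sets:
            out = [p + b for p in out for b in sorted(s)]
        return out


def _sets_to_text(sets) -> str:
    rev_iupac = {v: k for k, v in IUPAC.items()}
    parts = []
    for s in sets:
        if s in rev_iupac:
            parts.append(rev_iupac[s])
        else:
            parts.append("[" + "".join(sorted(s)) + "]")
    return "".join(parts)


def compile_pattern(text: str, name: str | None = None, variant_parent: str | None = None) -> MotifPattern:
    """Compile pattern text (IUPAC codes, N runs, [xy] alternatives) to a MotifPattern."""
    cleaned = text.replace(" ", "").replace("|", "").upper()
    sets: list[frozenset] = []
    i = 0
    while i < len(cleaned):
        ch = cleaned[i]
        if ch == "[":
            j = cleaned.find("]", i)
            if j == -1:
                raise ValueError(f"unbalanced bracket in pattern {text!r}")
            alts = cleaned[i + 1 : j]
            if not alts or any(c not in "ACGT" for c in alts):
                raise ValueError(f"invalid alternative group [{alts}] in pattern {text!r}")
            sets.append(frozenset(alts))
            i = j + 1
        elif ch == "]":
            raise ValueError(f"unbalanced bracket in pattern {text!r}")
        elif ch in IUPAC:
            sets.append(IUPAC[ch])
            i += 1
        else:
            raise ValueError(f"invalid code {ch!r} in pattern {text!r}")
    if not sets:
        raise ValueError("empty pattern")
    return MotifPattern(name or cleaned, cleaned, tuple(sets), variant_parent)


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # reference-strand coordinate of the leftmost matched base
    length: int
    orientation: str  # 'direct' | 'revcomp'; coding-strand relative for gene-resident hits
    partition: str  # label of the start base
    gene: str | None = None
    frame_offset: int | None = None  # (position within spliced CDS) mod 3, exonic hits only
    sequence: str = ""  # matched bases, coding-strand oriented for gene-resident hits

    @property
    def end(self) -> int:
        return self.start + self.length


class _GeneIndex:
    """Per-base gene lookup plus genome->spliced-CDS coordinate maps."""

    def __init__(self, rec: GenomeRecord):
        n = len(rec)
        self.gene_at = np.full(n, -1, dtype=np.int32)
        self.genes: list = []
        self.strand: dict[str, int] = {}
        self.spliced_index: dict[str, dict[int, int]] = {}
        cds_feats = sorted((f for f in rec.features if f.kind == "CDS"), key=lambda f: f.start)
        for gi, f in enumerate(cds_feats):
            self.genes.append(f.gene_name)
            self.strand[f.gene_name] = f.strand
            smap: dict[int, int] = {}
            idx = 0
            for a, b, strand in f.segments:  # segments are 5'->3' on the coding strand
                positions = range(b - 1, a - 1, -1) if strand == -1 else range(a, b)
                for pos in positions:
                    smap[pos] = idx
                    idx += 1
            self.spliced_index[f.gene_name] = smap
            for a, b, _ in f.segments:
                self.gene_at[a:b] = gi
        # intron bases belong to their host gene too
        for f in rec.features:
            if f.kind in ("intron", "intronic_ORF") and f.gene_name in self.strand:
                gi = self.genes.index(f.gene_name)
                for a, b, _ in f.segments:
                    sel = self.gene_at[a:b] == -1
                    self.gene_at[a:b][sel] = gi


def find_hits(motif: MotifPattern, rec: GenomeRecord, partition: PartitionMap | None = None) -> list[MotifHit]:
    """All matches of ``motif`` in both orientations, overlaps allowed.

    Each hit is labeled by the partition of its start base. Exonic hits
    carry the host gene, coding-strand orientation, and the frame offset of
    the hit's first coding-strand base within the spliced CDS. Hits of a
    self-reverse-complement pattern are reported in a single orientation.
    """
    if partition is None:
        from .genome_io import partition_genome

        partition = partition_genome(rec)
    n = len(rec)
    circular = rec.topology == "circular"
    search_seq = rec.seq + (rec.seq[: len(motif) - 1] if circular and len(motif) > 1 else "")

    gidx = _GeneIndex(rec)
    hits: list[MotifHit] = []
    orientations = [("direct", motif)]
    if not motif.self_revcomp:
        orientations.append(("revcomp", motif.reverse_complement()))
    for orient, pat in orientations:
        rx = re.compile(f"(?=({pat.to_regex()}))")
        for m in rx.finditer(search_seq):
            start = m.start()
            if start >= n:
                continue
            matched = m.group(1)
            label = LABEL_NAMES[int(partition.labels[start])]
            gene = None
            frame = None
            hit_orient = orient
            seq_out = matched
            gi = int(gidx.gene_at[start])
            if gi >= 0 and partition.labels[start] in (EXON, INTRON):
                gene = gidx.genes[gi]
                if gidx.strand[gene] == -1:
                    hit_orient = "revcomp" if orient == "direct" else "direct"
                    seq_out = revcomp(matched)
                if partition.labels[start] == EXON:
                    smap = gidx.spliced_index[gene]
                    first_coding = start if gidx.strand[gene] == 1 else (start + len(matched) - 1) % n
                    if first_coding in smap:
                        frame = smap[first_coding] % 3
            hits.append(MotifHit(motif.name, start, len(matched), hit_orient, label, gene, frame, seq_out))
    hits.sort(key=lambda h: (h.start, h.orientation))
    return hits


@dataclass
class PartitionedCounts:
    """Census of one or more (possibly nested) motif variants over a genome."""

    by_partition: pd.DataFrame  # motif x (partition, orientation) counts + totals
    per_gene_exon: pd.DataFrame  # gene x motif x orientation exon counts
    self_revcomp: dict[str, bool]
    hits: dict[str, list[MotifHit]] = field(repr=False, default_factory=dict)


def census(
    motifs: list[MotifPattern],
    rec: GenomeRecord,
    partition: PartitionMap | None = None,
    nested: bool = True,
) -> PartitionedCounts:
    """Tally motif occurrences by partition, orientation and gene.

    With ``nested=True`` (the default) a hit of a child variant is also
    counted by every ancestor, so counts form nested categories rather than
    mutually exclusive alternatives. Genes are ordered by genomic start,
    variants by declaration order.
    """
    if partition is None:
        from .genome_io import partition_genome

        partition = partition_genome(rec)
    raw: dict[str, dict] = {}
    for mp in motifs:
        raw[mp.name] = {h_key(h): h for h in find_hits(mp, rec, partition)}

    parents = {mp.name: mp.variant_parent for mp in motifs}
    final: dict[str, dict] = {name: dict(d) for name, d in raw.items()}
    if nested:
        for mp in motifs:
            anc = parents.get(mp.name)
            seen = set()
            while anc is not None and anc in final and anc not in seen:
                seen.add(anc)
                for key, h in raw[mp.name].items():
                    final[anc].setdefault(key, replace(h, motif=anc))
                anc = parents.get(anc)

    selfrc = {mp.name: mp.self_revcomp for mp in motifs}
    part_rows = []
    gene_rows = []
    gene_order: dict[str, int] = {}
    for f in sorted((f for f in rec.features if f.kind == "CDS"), key=lambda f: f.start):
        gene_order.setdefault(f.gene_name, f.start)
    for mp in motifs:
        hits = sorted(final[mp.name].values(), key=lambda h: h.start)
        row = {"motif": mp.name, "pattern": mp.pattern, "total": len(hits)}
        for lab in ("exon", "intron", "structural_RNA", "intergenic"):
            for orient in ("direct", "revcomp"):
                row[f"{lab}_{orient}"] = sum(1 for h in hits if h.partition == lab and h.orientation == orient)
        part_rows.append(row)
        per_gene: dict[tuple[str, str], int] = {}
        for h in hits:
            if h.partition == "exon" and h.gene is not None:
                per_gene[(h.gene, h.orientation)] = per_gene.get((h.gene, h.orientation), 0) + 1
        for (gene, orient), c in per_gene.items():
            gene_rows.append({"gene": gene, "motif": mp.name, "orientation": orient, "count": c})

    by_partition = pd.DataFrame(part_rows)
    per_gene_exon = pd.DataFrame(gene_rows, columns=["gene", "motif", "orientation", "count"])
    if len(per_gene_exon):
        per_gene_exon = per_gene_exon.sort_values(
            "gene", key=lambda s: s.map(lambda g: gene_order.get(g, 1 << 60)), kind="stable"
        ).reset_index(drop=True)
    counts = PartitionedCounts(by_partition, per_gene_exon, selfrc, {k: sorted(v.values(), key=lambda h: h.start) for k, v in final.items()})
    _assert_partition_sum(counts)
    return counts


def h_key(h: MotifHit) -> tuple[int, str]:
    """Identity of a physical hit: (start, reference-strand orientation is
    implied by sequence) — identical (start, orientation) reported once."""
    return (h.start, h.orientation)


def _assert_partition_sum(counts: PartitionedCounts) -> None:
    df = counts.by_partition
    split = sum(
        df[f"{lab}_{orient}"]
        for lab in ("exon", "intron", "structural_RNA", "intergenic")
        for orient in ("direct", "revcomp")
    )
    if len(df) and not (split == df["total"]).all():
        raise AssertionError("partition-split counts do not sum to whole-genome counts")


@dataclass
class RepeatArray:
    start: int
    end: int
    copies: dict[str, int]
    n_hits: int
    period: float
    interleaved: bool


def detect_arrays(
    hits: list[MotifHit],
    min_copies: int = 3,
    max_gap: int = 20,
    interleave_threshold: float = 0.8,
) -> list[RepeatArray]:
    """Maximal runs of >= min_copies hits with inter-hit gaps <= max_gap.

    For hits of two motifs, a run is classified interleaved when motif
    identities alternate in at least ``interleave_threshold`` of adjacent
    pairs. Reports array span, per-motif copy counts, and the median period
    (start-to-start distance).
    """
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: h.start)
    runs: list[list[MotifHit]] = [[hits[0]]]
    for h in hits[1:]:
        prev = runs[-1][-1]
        if h.start - prev.end <= max_gap:
            runs[-1].append(h)
        else:
            runs.append([h])
    arrays = []
    for run in runs:
        if len(run) < min_copies:
            continue
        copies: dict[str, int] = {}
        for h in run:
            copies[h.motif] = copies.get(h.motif, 0) + 1
        alternations = sum(1 for a, b in zip(run, run[1:]) if a.motif != b.motif)
        interleaved = len(copies) == 2 and alternations >= interleave_threshold * (len(run) - 1)
        periods = [b.start - a.start for a, b in zip(run, run[1:])]
        arrays.append(
            RepeatArray(
                start=run[0].start,
                end=run[-1].end,
                copies=copies,
                n_hits=len(run),
                period=float(np.median(periods)) if periods else 0.0,
                interleaved=interleaved,
            )
        )
    return arrays


def load_motif_config(path) -> list[MotifPattern]:
    """Load a motif set from JSON: a list of {name, pattern, parent} objects."""
    import json

    with open(path) as fh:
        entries = json.load(fh)
    return [compile_pattern(e["pattern"], e["name"], e.get("parent")) for e in entries]


__all__ = [
    "MotifPattern",
    "MotifHit",
    "PartitionedCounts",
    "RepeatArray",
    "compile_pattern",
    "find_hits",
    "census",
    "detect_arrays",
    "load_motif_config",
]
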