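"""Genome and annotation I/O plus exon/intron/intergenic partitioning.

All coordinates are 0-based half-open internally; GenBank and GFF3 use
1-based inclusive coordinates, converted exactly once at the I/O boundary.
A genome's topology (circular vs linear) is always explicit: the GenBank
LOCUS flag is honoured, FASTA defaults to linear unless overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._seq import gc_fraction, revcomp, validate_dna

STRUCTURAL_KINDS = frozenset({"tRNA", "rRNA"})
FEATURE_KINDS = frozenset({"CDS", "intron", "tRNA", "rRNA", "intronic_ORF"})

# per-base partition labels, ordered so that numeric max == precedence
INTERGENIC, INTRON, STRUCTURAL_RNA, EXON = 0, 1, 2, 3
LABEL_NAMES = {INTERGENIC: "intergenic", INTRON: "intron", STRUCTURAL_RNA: "structural_RNA", EXON: "exon"}


@dataclass
class Feature:
    """One annotated feature: a CDS, intron, tRNA, rRNA or intron-borne ORF.

    ``segments`` are (start, end, strand) triples in genome coordinates,
    ordered 5'->3' on the coding strand (i.e. descending genomic start for
    minus-strand features). An origin-spanning feature on a circular genome
    is stored as two (or more) segments that jointly wrap.
    """

    gene_name: str
    kind: str
    segments: list[tuple[int, int, int]]
    codon_start_phase: int = 0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.segments:
            raise ValueError(f"feature {self.gene_name}: no segments")
        strands = {s for _, _, s in self.segments}
        if len(strands) != 1:
            raise ValueError(f"feature {self.gene_name}: mixed-strand segments")
        for a, b, _ in self.segments:
            if not (0 <= a < b):
                raise ValueError(f"feature {self.gene_name}: bad segment ({a},{b})")

    @property
    def strand(self) -> int:
        return self.segments[0][2]

    @property
    def spliced_length(self) -> int:
        return sum(b - a for a, b, _ in self.segments)

    @property
    def start(self) -> int:
        return min(a for a, _, _ in self.segments)


@dataclass
class GenomeRecord:
    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        self.seq = validate_dna(self.seq, f"record {self.id}")
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def feature_by_gene(self, gene: str, kind: str = "CDS") -> Feature:
        for f in self.features:
            if f.gene_name == gene and f.kind == kind:
                return f
        available = sorted({f.gene_name for f in self.features if f.kind == kind})
        raise KeyError(f"no {kind} feature for gene {gene!r}; available: {', '.join(available)}")


@dataclass
class PartitionMap:
    """Per-base exon/structural-RNA/intron/intergenic labels for one genome."""

    labels: np.ndarray  # uint8 over {INTERGENIC, INTRON, STRUCTURAL_RNA, EXON}
    circular: bool
    intergenic_intervals: list[tuple[int, int]]  # (start, length); may wrap the origin

    @property
    def totals(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=4)
        return {LABEL_NAMES[i]: int(counts[i]) for i in range(4)}

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.labels)
        return {k: v / n for k, v in self.totals.items()}

    @property
    def coding_dna_bp(self) -> int:
        """Exon + structural-RNA bases (introns and intron-borne ORFs excluded)."""
        t = self.totals
        return t["exon"] + t["structural_RNA"]

    def label_at(self, pos: int) -> str:
        return LABEL_NAMES[int(self.labels[pos])]

    def to_bed(self, path, chrom: str = "genome") -> None:
        """Write the partition as BED intervals (0-based half-open, label in column 4)."""
        lab = self.labels
        breaks = np.flatnonzero(np.diff(lab)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(lab)]])
        with open(path, "w") as fh:
            for a, b in zip(starts, ends):
                fh.write(f"{chrom}\t{a}\t{b}\t{LABEL_NAMES[int(lab[a])]}\n")


def read_genome(path, fmt: str = None, topology_override: str | None = None) -> GenomeRecord:
    """Read a single-record FASTA or GenBank file into a GenomeRecord.

    GenBank features (CDS/tRNA/rRNA/intron) are converted to 0-based
    half-open segments; join()/complement() locations are decomposed into
    ordered strand-aware segments. Topology comes from the LOCUS line for
    GenBank; FASTA is linear unless ``topology_override`` says otherwise.
    """
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank") else "fasta"
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no records found (malformed {fmt}?)")
    rec = records[0]

    topology = "linear"
    if fmt == "genbank":
        topology = rec.annotations.get("topology", "linear")
    if topology_override is not None:
        topology = topology_override

    features: list[Feature] = []
    if fmt == "genbank":
        for sf in rec.features:
            kind = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "intron": "intron"}.get(sf.type)
            if kind is None:
                continue
            quals = sf.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
            phase = int(quals.get("codon_start", ["1"])[0]) - 1
            segs = []
            for part in sf.location.parts:
                segs.append((int(part.start), int(part.end), int(part.strand or 1)))
            strand = segs[0][2]
            segs.sort(key=lambda s: s[0], reverse=(strand == -1))
            features.append(Feature(name, kind, segs, codon_start_phase=phase if kind == "CDS" else 0))

    out = GenomeRecord(rec.id or path.stem, str(rec.seq), topology, features)
    for f in out.features:
        _check_cds_length(f)
    return out


def _check_cds_length(f: Feature) -> None:
    if f.kind == "CDS" and (f.spliced_length - f.codon_start_phase) % 3 != 0:
        warnings.warn(
            f"CDS {f.gene_name}: spliced length {f.spliced_length} not divisible by 3 "
            f"after phase {f.codon_start_phase}",
            stacklevel=3,
        )


def read_annotation(path, fmt: str = "gff3", genome_length: int | None = None) -> list[Feature]:
    """Read a GFF3 file into Feature objects.

    CDS/exon rows are grouped by their parent gene; introns are synthesized
    as the gaps between consecutive CDS/exon segments of the same gene.
    A gene split into several rows sharing one ID on a circular genome
    (origin-spanning) is reconstructed as a single wrapping feature when
    ``genome_length`` is given.
    """
    if fmt != "gff3":
        raise ValueError(f"unsupported annotation format {fmt!r}")
    genes: dict[str, dict] = {}
    standalone: list[Feature] = []
    gene_order: list[str] = []

    def _attrs(s: str) -> dict[str, str]:
        out = {}
        for item in s.strip().split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                out[k.strip()] = v.strip()
        return out

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            _, _, ftype, start, end, _, strand_s, phase_s, attr_s = cols
            a, b = int(start) - 1, int(end)
            strand = -1 if strand_s == "-" else 1
            attrs = _attrs(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID", f"gene{lineno}")
                entry = genes.setdefault(gid, {"name": attrs.get("Name", gid), "strand": strand, "cds": [], "phase": 0})
                if gid not in gene_order:
                    gene_order.append(gid)
                if entry["strand"] != strand:
                    raise ValueError(f"{path}:{lineno}: gene {gid} declared on both strands")
            elif ftype in ("CDS", "exon"):
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    raise ValueError(f"{path}:{lineno}: {ftype} row without a known parent gene")
                entry = genes[parent]
                if strand != entry["strand"]:
                    raise ValueError(f"{path}:{lineno}: mixed-strand segments in gene {parent}")
                if ftype == "CDS" and not entry["cds"]:
                    entry["phase"] = int(phase_s) if phase_s.isdigit() else 0
                entry["cds"].append((a, b, strand))
            elif ftype in ("tRNA", "rRNA"):
                name = attrs.get("Name") or attrs.get("ID") or f"{ftype}{lineno}"
                standalone.append(Feature(name, ftype, [(a, b, strand)]))
            elif ftype == "intronic_ORF":
                name = attrs.get("Name") or attrs.get("ID") or f"orf{lineno}"
                standalone.append(Feature(name, "intronic_ORF", [(a, b, strand)]))
            # other row types (region, mRNA, ...) are ignored

    features: list[Feature] = []
    for gid in gene_order:
        entry = genes[gid]
        segs = sorted(set(entry["cds"]))
        if not segs:
            continue
        strand = entry["strand"]
        wraps = (
            genome_length is not None
            and len(segs) >= 2
            and segs[0][0] == 0
            and segs[-1][1] == genome_length
        )
        if wraps:
            # chain the 3' wrap segment after the one ending at the origin
            segs = segs[-1:] + segs[:-1]
        if strand == -1:
            segs = segs[::-1]
        features.append(Feature(entry["name"], "CDS", segs, codon_start_phase=entry["phase"]))
        # introns: gaps between consecutive segments along the gene's chain.
        # For an origin-spanning gene the chain is the genomically sorted
        # order rotated so it starts with the 5'-side segment ending at the
        # origin; the junction crossing position 0 is then explicit and
        # abutting segments there yield no intron.
        chain = sorted(entry["cds"])
        if wraps:
            chain = chain[-1:] + chain[:-1]
        for (_, b1, _), (a2, _, _) in zip(chain, chain[1:]):
            if a2 > b1:
                features.append(Feature(entry["name"], "intron", [(b1, a2, strand)]))
            elif a2 <= b1 and wraps and b1 == genome_length:
                if a2 > 0:  # intron hanging over the origin on the 3' side
                    features.append(Feature(entry["name"], "intron", [(0, a2, strand)]))
    features.extend(standalone)
    for f in features:
        _check_cds_length(f)
    return features


def write_gff3(rec: GenomeRecord, path) -> None:
    """Write the record's features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {rec.id} 1 {len(rec)}\n")
        for f in rec.features:
            strand = "-" if f.strand == -1 else "+"
            if f.kind == "CDS":
                a = min(s[0] for s in f.segments)
                b = max(s[1] for s in f.segments)
                fh.write(f"{rec.id}\torgscape\tgene\t{a + 1}\t{b}\t.\t{strand}\t.\tID={f.gene_name};Name={f.gene_name}\n")
                for i, (sa, sb, _) in enumerate(sorted(f.segments)):
                    phase = f.codon_start_phase if i == 0 else 0
                    fh.write(
                        f"{rec.id}\torgscape\tCDS\t{sa + 1}\t{sb}\t.\t{strand}\t{phase}\t"
                        f"ID={f.gene_name}.cds{i};Parent={f.gene_name}\n"
                    )
            elif f.kind in ("tRNA", "rRNA", "intronic_ORF"):
                for sa, sb, _ in f.segments:
                    fh.write(f"{rec.id}\torgscape\t{f.kind}\t{sa + 1}\t{sb}\t.\t{strand}\t.\tID={f.gene_name};Name={f.gene_name}\n")
            # explicit intron rows are omitted: introns are re-synthesized on read


def write_fasta(rec: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        topo = "circular" if rec.topology == "circular" else "linear"
        fh.write(f">{rec.id} topology={topo}\n")
        for i in range(0, len(rec.seq), 70):
            fh.write(rec.seq[i : i + 70] + "\n")


def partition_genome(rec: GenomeRecord) -> PartitionMap:
    """Label every base exon / structural_RNA / intron / intergenic.

    Overlap precedence is exon > structural_RNA > intron > intergenic, so
    coding DNA (exon + structural RNA) excludes introns and the ORFs inside
    them while tRNA/rRNA bases count as coding. Intergenic intervals honour
    the declared topology: a circular genome has no artificial break at
    position 0.
    """
    n = len(rec)
    labels = np.zeros(n, dtype=np.uint8)
    for f in rec.features:
        if f.kind == "CDS":
            code = EXON
        elif f.kind in STRUCTURAL_KINDS:
            code = STRUCTURAL_RNA
        else:  # intron, intronic_ORF
            code = INTRON
        for a, b, _ in f.segments:
            if b > n:
                raise ValueError(f"feature {f.gene_name} segment ({a},{b}) outside genome of length {n}")
            np.maximum(labels[a:b], code, out=labels[a:b])

    circular = rec.topology == "circular"
    inter = labels == INTERGENIC
    intervals: list[tuple[int, int]] = []
    if inter.all():
        intervals.append((0, n))
    elif inter.any():
        diff = np.diff(inter.astype(np.int8))
        starts = list(np.flatnonzero(diff == 1) + 1)
        ends = list(np.flatnonzero(diff == -1) + 1)
        if inter[0]:
            starts.insert(0, 0)
        if inter[-1]:
            ends.append(n)
        intervals = [(int(a), int(b - a)) for a, b in zip(starts, ends)]
        if circular and len(intervals) > 1 and intervals[0][0] == 0 and sum(intervals[-1]) == n:
            # merge the run touching position 0 with the run touching the end
            first, last = intervals[0], intervals[-1]
            intervals = [(last[0], last[1] + first[1])] + intervals[1:-1]
    return PartitionMap(labels=labels, circular=circular, intergenic_intervals=intervals)


def spliced_cds(rec: GenomeRecord, gene: str) -> str:
    """Spliced, phase-trimmed CDS of ``gene``, 5'->3' on the coding strand."""
    f = rec.feature_by_gene(gene, "CDS")
    parts = []
    for a, b, strand in f.segments:
        s = rec.seq[a:b]
        parts.append(revcomp(s) if strand == -1 else s)
    cds = "".join(parts)
    return cds[f.codon_start_phase :]


__all__ = [
    "GenomeRecord",
    "Feature",
    "PartitionMap",
    "read_genome",
    "read_annotation",
    "write_gff3",
    "write_fasta",
    "partition_genome",
    "spliced_cds",
    "gc_fraction",
    "LABEL_NAMES",
    "EXON",
    "INTRON",
    "STRUCTURAL_RNA",
    "INTERGENIC",
]
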