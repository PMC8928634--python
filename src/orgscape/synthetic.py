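"""Synthetic annotated organellar genomes with planted, manifest-recorded
repeat structures.

The generator emulates the architecture this package analyses: a circular
(or linear) genome of ~100-400 kbp with GC-controlled i.i.d. intergenic
background, annotated genes (multi-exon CDSs with introns, tRNAs, rRNAs),
and planted repeats in tandem, interspersed, interleaved and palindromic
arrangements, plus frame-safe repeat insertions inside exons. Every
realized copy (coordinates, orientation, degenerate-position choices) is
recorded in a ground-truth manifest, so downstream scanners can be tested
for exact recovery without any external data.

Two deliberate departures from a plain random background keep the planted
truth unambiguous:

* guard flanks — the bases immediately flanking a planted block are set so
  a planted palindrome can never extend by chance into the background;
* scrubbing — after assembly, accidental background occurrences of any
  planted motif (either orientation) are mutated away, so the manifest
  lists *all* occurrences, not merely the planted ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import STOP_CODONS, revcomp
from .genome_io import Feature, GenomeRecord, write_fasta, write_gff3
from .motifs import MotifPattern, compile_pattern, find_hits

SENSE_CODONS = sorted(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOP_CODONS
)

ARRANGEMENTS = ("tandem_array", "interspersed", "interleaved", "exonic_insertion")


@dataclass
class GeneModel:
    name: str
    exon_lengths: list[int]
    strand: int = 1
    kind: str = "CDS"  # CDS | tRNA | rRNA
    intron_lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.kind == "CDS":
            if sum(self.exon_lengths) % 3 != 0:
                raise ValueError(f"gene {self.name}: CDS length must be divisible by 3")
            if not self.intron_lengths:
                self.intron_lengths = [120] * (len(self.exon_lengths) - 1)
            if len(self.intron_lengths) != len(self.exon_lengths) - 1:
                raise ValueError(f"gene {self.name}: need n_exons-1 intron lengths")


@dataclass
class PlantDirective:
    motif: str
    arrangement: str
    copies: int
    name: str = ""
    motif2: str | None = None  # second motif of an interleaved pair
    max_gap: int = 0  # bp between consecutive copies in arrays
    target: str = "intergenic"  # 'intergenic' | 'intron:<gene>' | gene name (exonic_insertion)
    orientation_mix: float = 1.0  # fraction of copies planted in direct orientation

    def __post_init__(self):
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.arrangement == "interleaved" and not self.motif2:
            raise ValueError("interleaved arrangement needs motif2")
        if not self.name:
            self.name = f"{self.arrangement}:{self.motif[:12]}"
        if self.arrangement == "exonic_insertion" and len(compile_pattern(self.motif)) % 3 != 0:
            raise ValueError("exonic insertion length must be divisible by 3")


@dataclass
class GenomeSpec:
    length: int
    topology: str = "circular"
    background_gc: float = 0.37
    gene_models: list[GeneModel] = field(default_factory=list)
    repeat_plan: list[PlantDirective] = field(default_factory=list)
    seed: int = 0
    genome_id: str = "synthetic"


@dataclass
class TruthManifest:
    spec: dict
    directives: list[dict]
    genes: list[dict]

    def counts(self) -> dict[str, int]:
        return {d["name"]: len(d["instances"]) for d in self.directives}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"spec": self.spec, "directives": self.directives, "genes": self.genes}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["spec"], d["directives"], d["genes"])


def _draw_background(rng, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _realize(pattern: MotifPattern, rng) -> str:
    return "".join(sorted(s)[rng.integers(len(s))] for s in pattern.sets)


def _realize_codons(pattern: MotifPattern, rng, allowed: set[str]) -> str:
    """Realize a degenerate pattern codon-wise, drawing only allowed codons."""
    out = []
    for i in range(0, len(pattern.sets), 3):
        triplet_sets = pattern.sets[i : i + 3]
        options = [
            a + b + c
            for a in sorted(triplet_sets[0])
            for b in sorted(triplet_sets[1])
            for c in sorted(triplet_sets[2])
        ]
        options = [t for t in options if t in allowed]
        if not options:
            raise ValueError(f"pattern {pattern.pattern}: codon {i // 3} has no allowed realization")
        out.append(options[rng.integers(len(options))])
    return "".join(out)


class _Assembler:
    def __init__(self, spec: GenomeSpec, rng, allowed_codons: set[str]):
        self.spec = spec
        self.rng = rng
        self.allowed = allowed_codons
        self.occupied = np.zeros(spec.length, dtype=bool)
        self.seq = _draw_background(rng, spec.length, spec.background_gc)
        self.features: list[Feature] = []
        self.gene_entries: list[dict] = []
        self.directive_entries: list[dict] = []
        self.intron_spans: dict[str, list[tuple[int, int]]] = {}

    # -- genes ---------------------------------------------------------

    def build_gene(self, gm: GeneModel, insertions: list[dict]) -> tuple[np.ndarray, dict]:
        """Return (genomic block, layout info). Insertions are dicts with
        realized codon strings and chosen spliced codon indices."""
        rng = self.rng
        if gm.kind != "CDS":
            block = _draw_background(rng, gm.exon_lengths[0], 0.5)
            return block, {"exons_block": [(0, len(block))], "spliced_len": len(block)}
        n_codons = sum(gm.exon_lengths) // 3
        codons = ["ATG"] + [SENSE_CODONS[rng.integers(len(SENSE_CODONS))] for _ in range(n_codons - 2)] + ["TAA"]
        exon_lengths = list(gm.exon_lengths)
        if len({d["codon_index"] for d in insertions}) != len(insertions):
            raise ValueError(f"gene {gm.name}: colliding insertion sites")
        # apply insertions at distinct interior codon boundaries, 3'-most first
        # so earlier indices stay valid; final spliced positions then include
        # the shift from insertions 5' of each site
        for ins in sorted(insertions, key=lambda d: -d["codon_index"]):
            ci = ins["codon_index"]
            codons[ci:ci] = [ins["codons"][i : i + 3] for i in range(0, len(ins["codons"]), 3)]
        shift = 0
        for ins in sorted(insertions, key=lambda d: d["codon_index"]):
            ins["spliced_pos"] = (ins["codon_index"] + shift) * 3
            shift += len(ins["codons"]) // 3
        # grow the exon containing each insertion point
        cum = np.cumsum(exon_lengths)
        for ins in insertions:
            p = ins["spliced_pos"]
            ei = int(np.searchsorted(cum, p, side="right"))
            ei = min(ei, len(exon_lengths) - 1)
            exon_lengths[ei] += len(ins["codons"])
            cum = np.cumsum(exon_lengths)
        spliced = "".join(codons)
        assert sum(exon_lengths) == len(spliced)
        # coding-orientation block: exon1 intron1 exon2 ...
        parts, exons_block = [], []
        pos = 0
        off = 0
        for i, el in enumerate(exon_lengths):
            parts.append(spliced[off : off + el])
            exons_block.append((pos, pos + el))
            pos += el
            off += el
            if i < len(exon_lengths) - 1:
                il = gm.intron_lengths[i]
                parts.append("".join("ACGT"[b] for b in rng.integers(0, 4, il)))
                pos += il
        block = np.frombuffer("".join(parts).encode(), dtype=np.uint8).copy()
        if gm.strand == -1:
            block = np.frombuffer(revcomp("".join(parts)).encode(), dtype=np.uint8).copy()
        return block, {
            "exons_block": exons_block,
            "spliced_len": len(spliced),
            "block_len": len(block),
            "insertions": insertions,
        }

    def place_genes(self, gene_insertions: dict[str, list[dict]]):
        spec, rng = self.spec, self.rng
        blocks = []
        for gm in spec.gene_models:
            block, layout = self.build_gene(gm, gene_insertions.get(gm.name, []))
            blocks.append((gm, block, layout))
        total = sum(len(b) for _, b, _ in blocks)
        n_gaps = len(blocks) + 1
        slack = spec.length - total - 2 * n_gaps  # >= 2 bp guard per gap
        if blocks and slack < 0:
            raise ValueError(f"infeasible packing: genes need {total} bp of {spec.length}")
        # random gap sizes: 2 + multinomial split of the slack
        if blocks:
            props = rng.dirichlet(np.ones(n_gaps))
            gaps = (props * slack).astype(int)
            gaps[-1] += slack - gaps.sum()
            gaps += 2
            pos = int(gaps[0])
            for (gm, block, layout), gap_next in zip(blocks, gaps[1:]):
                self._write_gene(gm, block, layout, pos)
                pos += len(block) + int(gap_next)

    def _write_gene(self, gm: GeneModel, block: np.ndarray, layout: dict, start: int):
        n = len(block)
        self.seq[start : start + n] = block
        self.occupied[start : start + n] = True
        if gm.kind != "CDS":
            self.features.append(Feature(gm.name, gm.kind, [(start, start + n, gm.strand)]))
            self.gene_entries.append(
                {"name": gm.name, "kind": gm.kind, "strand": gm.strand, "segments": [[start, start + n]], "insertions": []}
            )
            return
        segs = []
        for a, b in layout["exons_block"]:
            if gm.strand == 1:
                segs.append((start + a, start + b, 1))
            else:
                segs.append((start + n - b, start + n - a, -1))
        # order 5'->3' on the coding strand
        segs.sort(key=lambda s: s[0], reverse=(gm.strand == -1))
        self.features.append(Feature(gm.name, "CDS", segs))
        introns = []
        genomic = sorted((a, b) for a, b, _ in segs)
        for (a1, b1), (a2, _) in zip(genomic, genomic[1:]):
            if a2 > b1:
                self.features.append(Feature(gm.name, "intron", [(b1, a2, gm.strand)]))
                introns.append((b1, a2))
        self.intron_spans[gm.name] = introns
        for ins in layout["insertions"]:
            p = ins["spliced_pos"]
            L = len(ins["codons"])
            if gm.strand == 1:
                g = self._spliced_to_block(layout, p)
                ins["genome_start"] = start + g
            else:
                g = self._spliced_to_block(layout, p + L - 1)
                ins["genome_start"] = start + n - g - 1
            ins["genome_end"] = ins["genome_start"] + L
        self.gene_entries.append(
            {
                "name": gm.name,
                "kind": "CDS",
                "strand": gm.strand,
                "segments": [[a, b] for a, b, _ in segs],
                "insertions": [
                    {k: ins[k] for k in ("directive", "codons", "spliced_pos", "genome_start", "genome_end", "orientation")}
                    for ins in layout["insertions"]
                ],
            }
        )

    @staticmethod
    def _spliced_to_block(layout: dict, p: int) -> int:
        off = 0
        for a, b in layout["exons_block"]:
            if p < off + (b - a):
                return a + (p - off)
            off += b - a
        raise AssertionError("spliced position outside exons")

    # -- plants --------------------------------------------------------

    def _free_slot(self, length: int, region: tuple[int, int] | None = None) -> int:
        """Rejection-sample an unoccupied start for a planted block.

        Intergenic placements keep a 50 bp clearance from anything already
        placed, so independently planted blocks can never sit close enough
        to merge into one apparent arrangement; placements targeted into an
        intron only keep the 1 bp guard margin (clusters there are meant to
        be dense)."""
        rng = self.rng
        clearance = 1 if region else 50
        lo, hi = region if region else (0, self.spec.length)
        if hi - lo < length + 2:
            raise ValueError("target region too small for planted block")
        for _ in range(10_000):
            start = int(rng.integers(lo + 1, hi - length))
            w0 = max(0, start - clearance)
            if not self.occupied[w0 : start + length + clearance].any():
                return start
        raise ValueError("could not place planted block (genome too crowded)")

    def _write_block(self, start: int, text: str):
        n = len(text)
        self.seq[start : start + n] = np.frombuffer(text.encode(), dtype=np.uint8)
        self.occupied[start : start + n] = True
        # guard flanks: flanking bases must not be complementary, so a
        # planted palindrome cannot extend by chance
        if start > 0:
            self.seq[start - 1] = ord("A")
            self.occupied[start - 1] = True
        if start + n < self.spec.length:
            self.seq[start + n] = ord("A")
            self.occupied[start + n] = True

    def plant(self, d: PlantDirective):
        rng = self.rng
        pat = compile_pattern(d.motif)
        pat2 = compile_pattern(d.motif2) if d.motif2 else None
        region = None
        if d.target.startswith("intron:"):
            gene = d.target.split(":", 1)[1]
            spans = self.intron_spans.get(gene)
            if not spans:
                raise ValueError(f"directive {d.name}: gene {gene!r} has no intron")
            region = spans[0]
            self.occupied[region[0] : region[1]] = False  # intron interior is plantable
        instances = []

        def one_copy(p: MotifPattern) -> tuple[str, str]:
            direct = rng.random() < d.orientation_mix
            realized = _realize(p, rng)
            return (realized if direct else revcomp(realized)), ("direct" if direct else "revcomp")

        if d.arrangement in ("tandem_array", "interleaved"):
            pieces, meta = [], []
            pos = 0
            for i in range(d.copies):
                p = pat if (d.arrangement == "tandem_array" or i % 2 == 0) else pat2
                text, orient = one_copy(p)
                # inter-copy fillers are all-A guards (an A next to an A can
                # never extend a planted palindrome, since A pairs with T)
                gap = int(rng.integers(min(1, d.max_gap), d.max_gap + 1)) if i else 0
                filler = "A" * gap
                pieces.append(filler + text)
                pos += gap
                meta.append({"offset": pos, "len": len(text), "orientation": orient, "realized": text,
                             "motif": p.pattern})
                pos += len(text)
            block = "".join(pieces)
            start = self._free_slot(len(block), region)
            self._write_block(start, block)
            for m in meta:
                instances.append(
                    {"start": start + m["offset"], "end": start + m["offset"] + m["len"],
                     "orientation": m["orientation"], "realized": m["realized"], "motif": m["motif"]}
                )
        elif d.arrangement == "interspersed":
            for _ in range(d.copies):
                text, orient = one_copy(pat)
                start = self._free_slot(len(text), region)
                self._write_block(start, text)
                instances.append({"start": start, "end": start + len(text), "orientation": orient,
                                  "realized": text, "motif": pat.pattern})
        else:
            raise AssertionError("exonic_insertion handled before assembly")
        if region is not None:
            self.occupied[region[0] : region[1]] = True
        self.directive_entries.append(
            {"name": d.name, "motif": d.motif, "motif2": d.motif2, "arrangement": d.arrangement,
             "copies": d.copies, "target": d.target, "instances": instances}
        )


def build_genome(spec: GenomeSpec, allowed_codons: set[str] | None = None) -> tuple[GenomeRecord, TruthManifest]:
    """Realize a GenomeSpec deterministically into a genome plus manifest.

    ``allowed_codons`` constrains the realized codons of exonic insertions
    (default: all sense codons, i.e. stops excluded), emulating the
    selection signature of tolerated in-frame insertions.
    """
    rng = np.random.default_rng(spec.seed)
    allowed = set(allowed_codons) if allowed_codons is not None else set(SENSE_CODONS)
    if spec.topology not in ("circular", "linear"):
        raise ValueError(f"bad topology {spec.topology!r}")

    gene_names = {g.name for g in spec.gene_models}
    planted_total = 0
    for d in spec.repeat_plan:
        if d.arrangement == "exonic_insertion" and d.target not in gene_names:
            raise ValueError(f"directive {d.name}: target gene {d.target!r} not in gene_models")
        if d.arrangement != "exonic_insertion":
            unit = len(compile_pattern(d.motif))
            planted_total += d.copies * (unit + d.max_gap)
    gene_total = sum(sum(g.exon_lengths) + sum(g.intron_lengths) for g in spec.gene_models)
    if planted_total + gene_total > spec.length:
        raise ValueError(
            f"infeasible packing: {planted_total + gene_total} bp of genes+plants exceed genome length {spec.length}"
        )

    # realize exonic insertions first (they reshape genes)
    gene_insertions: dict[str, list[dict]] = {}
    exonic_entries: list[dict] = []
    for d in spec.repeat_plan:
        if d.arrangement != "exonic_insertion":
            continue
        pat = compile_pattern(d.motif)
        gm = next(g for g in spec.gene_models if g.name == d.target)
        n_codons = sum(gm.exon_lengths) // 3
        if n_codons < d.copies + 2:
            raise ValueError(f"directive {d.name}: gene {d.target} too short for {d.copies} insertions")
        sites = rng.choice(np.arange(1, n_codons - 1), size=d.copies, replace=False)
        entry = {"name": d.name, "motif": d.motif, "motif2": None, "arrangement": d.arrangement,
                 "copies": d.copies, "target": d.target, "instances": []}
        for ci in sorted(int(s) for s in sites):
            direct = rng.random() < d.orientation_mix
            reading_pat = pat if direct else pat.reverse_complement()
            codons = _realize_codons(reading_pat, rng, allowed)
            gene_insertions.setdefault(d.target, []).append(
                {"directive": d.name, "codon_index": ci, "codons": codons,
                 "orientation": "direct" if direct else "revcomp"}
            )
        exonic_entries.append(entry)

    asm = _Assembler(spec, rng, allowed)
    asm.place_genes(gene_insertions)
    for d in spec.repeat_plan:
        if d.arrangement != "exonic_insertion":
            asm.plant(d)

    # fill exonic directive instances now that genome coordinates exist;
    # 'realized' is always the reference-strand slice, so for a minus-strand
    # gene it is the reverse complement of the inserted coding codons
    for entry in exonic_entries:
        for ge in asm.gene_entries:
            for ins in ge["insertions"]:
                if ins["directive"] == entry["name"]:
                    ref = ins["codons"] if ge["strand"] == 1 else revcomp(ins["codons"])
                    entry["instances"].append(
                        {"start": ins["genome_start"], "end": ins["genome_end"],
                         "orientation": ins["orientation"], "realized": ref, "motif": entry["motif"]}
                    )
        entry["instances"].sort(key=lambda i: i["start"])
        asm.directive_entries.append(entry)

    rec = GenomeRecord(spec.genome_id, asm.seq.tobytes().decode(), spec.topology, asm.features)
    manifest = TruthManifest(
        spec={"length": spec.length, "topology": spec.topology, "background_gc": spec.background_gc,
              "seed": spec.seed, "genome_id": spec.genome_id},
        directives=asm.directive_entries,
        genes=asm.gene_entries,
    )
    rec = _scrub_accidental_matches(rec, manifest, rng, allowed)
    return rec, manifest


def _scrub_accidental_matches(rec: GenomeRecord, manifest: TruthManifest, rng, allowed: set[str]) -> GenomeRecord:
    """Mutate away background occurrences of planted motifs not in the manifest."""
    patterns: dict[str, MotifPattern] = {}
    for d in manifest.directives:
        for m in filter(None, (d["motif"], d.get("motif2"))):
            p = compile_pattern(m)
            patterns[p.pattern] = p
    if not patterns:
        return rec
    n = len(rec.seq)
    covered = np.zeros(n, dtype=bool)
    for d in manifest.directives:
        for i in d["instances"]:
            covered[i["start"] : i["end"]] = True
    seq = np.frombuffer(rec.seq.encode(), dtype=np.uint8).copy()

    for _ in range(50):
        current = GenomeRecord(rec.id, seq.tobytes().decode(), rec.topology, rec.features)
        dirty = False
        for pat in patterns.values():
            for h in find_hits(pat, current):
                # a match is ground truth iff it lies entirely inside planted copies
                if covered[h.start : h.end].all() if h.end <= n else covered[np.arange(h.start, h.end) % n].all():
                    continue
                dirty = True
                span = [p % n for p in range(h.start, h.end) if not covered[p % n]]
                pos = span[len(span) // 2]
                _mutate(seq, pos, rng, manifest, allowed)
        if not dirty:
            break
    else:
        raise ValueError("scrubbing did not converge; motifs too dense for this genome")
    return GenomeRecord(rec.id, seq.tobytes().decode(), rec.topology, rec.features)


def _mutate(seq: np.ndarray, pos: int, rng, manifest: TruthManifest, allowed: set[str]) -> None:
    host = next(((a, b, g) for g in manifest.genes if g["kind"] == "CDS"
                 for a, b in g["segments"] if a <= pos < b), None)
    if host is None:
        choices = [b for b in b"ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
        return
    # inside a CDS exon: replace the containing codon with a different allowed codon
    a, b, gene = host
    strand = gene["strand"]
    # spliced index of pos within this gene
    idx = 0
    for sa, sb in gene["segments"]:
        if (sa, sb) == (a, b):
            idx += (pos - sa) if strand == 1 else (sb - 1 - pos)
            break
        idx += sb - sa
    codon_i = idx // 3
    # locate the codon's three genome positions via the segment map
    flat = []
    for sa, sb in gene["segments"]:
        flat.extend(range(sa, sb) if strand == 1 else range(sb - 1, sa - 1, -1))
    cpos = flat[codon_i * 3 : codon_i * 3 + 3]
    cur = "".join(chr(seq[p]) if strand == 1 else revcomp(chr(seq[p])) for p in cpos)
    options = [c for c in sorted(allowed) if c != cur]
    new = options[rng.integers(len(options))]
    for p, basech in zip(cpos, new if strand == 1 else new):
        seq[p] = ord(basech) if strand == 1 else ord(revcomp(basech))


def plastome_like_spec(seed: int, length: int = 100_000) -> GenomeSpec:
    """A ~100 kbp circular genome emulating a repeat-bloated plastome.

    Defaults mirror the architecture this package targets: AT-rich (37% GC)
    background, a handful of multi-exon genes on both strands (one with a
    long intron hosting a repeat cluster), an abundant imperfect palindrome
    planted interspersed and interleaved with a 12-mer partner, a 32-mer
    intron cluster, and frame-safe 60-nt composite insertions inside two
    genes' exons.
    """
    return GenomeSpec(
        length=length,
        topology="circular",
        background_gc=0.37,
        seed=seed,
        genome_id=f"synthetic_plastome_s{seed}",
        gene_models=[
            GeneModel("rpoC2x", [900, 600], strand=1),
            GeneModel("ftsHx", [1200], strand=-1),
            GeneModel("atpAx", [500, 400], strand=1, intron_lengths=[1500]),
            GeneModel("rpoC1x", [750], strand=-1),
            GeneModel("trnX", [80], kind="tRNA"),
            GeneModel("rrnLx", [1500], kind="rRNA", strand=-1),
        ],
        repeat_plan=[
            PlantDirective("CAAACCAGTNNACTGGTTAG", "interspersed", 25, name="ip_interspersed"),
            PlantDirective("TAACTAAACTTC", "tandem_array", 40, name="partner_tandem", max_gap=3),
            PlantDirective("CAAACCAGTNNACTGGTTAG", "interleaved", 14, name="ip_interleaved",
                           motif2="TAACTACTT", max_gap=5),
            PlantDirective("TGGTTAGTAACTAAACTTCCAAACCAGTAAAC", "interspersed", 20,
                           name="intron_cluster", target="intron:atpAx"),
            PlantDirective("AAAGATAAGTCAGCAGAGCTGAC[AT]TCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT",
                           "exonic_insertion", 4, name="composite60_rpoC2", target="rpoC2x"),
            PlantDirective("AAAGATAAGTCAGCAGAGCTGAC[AT]TCCAGACCACTAAAGTGGTCAGTAACTAAAAGTTAT",
                           "exonic_insertion", 2, name="composite60_ftsH", target="ftsHx"),
        ],
    )


def expected_pattern_counts(manifest: TruthManifest, patterns: list[MotifPattern]) -> dict[str, int]:
    """Ground-truth genome-wide occurrence count per pattern, from the
    manifest alone.

    After scrubbing, a pattern occurs in the genome exactly where it occurs
    inside planted copies, so the expected census total is the number of
    matches (both orientations, overlaps allowed) within the concatenated
    realized strings of each contiguous run of planted instances.
    """
    import re

    instances = sorted(
        (i["start"], i["end"], i["realized"]) for d in manifest.directives for i in d["instances"]
    )
    runs: list[str] = []
    prev_end = None
    for start, end, text in instances:
        if runs and start == prev_end:
            runs[-1] += text
        else:
            runs.append(text)
        prev_end = end
    counts: dict[str, int] = {}
    for pat in patterns:
        rxs = [re.compile(f"(?=({pat.to_regex()}))")]
        if not pat.self_revcomp:
            rxs.append(re.compile(f"(?=({pat.reverse_complement().to_regex()}))"))
        total = 0
        for run in runs:
            for rx in rxs:
                total += sum(1 for _ in rx.finditer(run))
        counts[pat.name] = total
    return counts


def write_genome(rec: GenomeRecord, manifest: TruthManifest, out_dir) -> dict[str, Path]:
    """Emit FASTA + GFF3 + JSON manifest; round-trips losslessly through genome_io."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / f"{rec.id}.fasta",
        "gff3": out / f"{rec.id}.gff3",
        "manifest": out / f"{rec.id}.manifest.json",
    }
    write_fasta(rec, paths["fasta"])
    write_gff3(rec, paths["gff3"])
    manifest.to_json(paths["manifest"])
    return paths


__all__ = [
    "GeneModel",
    "PlantDirective",
    "GenomeSpec",
    "TruthManifest",
    "build_genome",
    "write_genome",
    "plastome_like_spec",
    "expected_pattern_counts",
]
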