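# orgscape

Repeat landscapes, codon-rarity impact and G-quadruplex density in
organellar genomes.

Some plastid and mitochondrial genomes — most dramatically in
chlamydomonadalean green algae — balloon to hundreds of kilobases not by
gaining genes but by accumulating short sequence repeats: tandem arrays,
interspersed copies, imperfect palindromes, and interleaved composites of
all three. In extreme cases the repeats invade introns and even exons,
where only insertions that keep the reading frame open and avoid rare
codons survive; GC-rich variants of the same phenomenon carry dense
potential G-quadruplex-forming sequences (PQS). `orgscape` is a toolkit
for quantifying this landscape on any annotated organellar genome, built
for comparative genomicists who have a FASTA/GenBank record (plus GFF3 if
the annotation is separate) and want the survey numbers reproducibly.

## What it computes

* **Partition** — per-base exon / structural-RNA / intron / intergenic
  labels (precedence exon > structural RNA > intron), coding-DNA and
  intergenic fractions, intergenic interval lengths; circular topology
  respected throughout.
* **Imperfect palindromes** — all maximal sites `L|S|R` with
  Hamming(L, revcomp(R)) ≤ m, arms 8–100 bp, spacers 0–10 bp, m ≤ 1 by
  default; abundance ranking by spacer-masked canonical form, with exon
  occupancy.
* **Degenerate motif census** — IUPAC + `[xy]` patterns matched in both
  orientations with overlaps, tallied by partition × orientation × gene,
  with nested variant hierarchies, exonic frame offsets, and
  tandem/interleaved array detection.
* **Frame impact** — codon usage of the CDS set; cumulative rarity
  categories (the least-used codons jointly under 2/4/10/20% of all
  codons; the most-used jointly over 50%); six-frame translation of a
  degenerate motif with (min, max) stop / rare-codon / rare-amino-acid
  counts over all expansions; descriptive orientation × phase bias report
  for exonic repeat copies.
* **PQS** — G4Hunter scoring (±min(run, 4) per base in G/C runs), sliding
  window 25, threshold 1.2, merged-region and raw-window densities per
  1000 bp.
* **Composition extras** — GC by partition, codon GC and GC3, GARP
  amino-acid fraction, terminal-direct-repeat circularisation, and
  dotplot word-match coordinates (word 15) for self/cross similarity
  plots.
* **Synthetic genomes** — a generator that plants all of the above with a
  ground-truth manifest, used by the test suite for exact recovery checks.

## Worked example

```python
from orgscape import *
from orgscape.palindromes import ScanConfig
from orgscape.synthetic import plastome_like_spec, build_genome

rec, manifest = build_genome(plastome_like_spec(seed=1))
print(rec.id, len(rec), rec.topology)

pm = partition_genome(rec)
print({k: round(v, 3) for k, v in pm.fractions.items()})

hits = scan_palindromes(rec, ScanConfig(8, 100, 0, 10, 1))
print(rank_ips(hits, "spacer_masked", pm).head(3).to_string(index=False))

regions, density = find_pqs(rec)
print(f"{len(regions)} PQS, {density:.2f} per 1000 bp")
```

prints

```
synthetic_plastome_s1 100000 circular
{'intergenic': 0.921, 'intron': 0.016, 'structural_RNA': 0.016, 'exon': 0.047}
                  form  arm_len  spacer_len  mismatches  count  exon_count
CAAACCAGT|NN|ACTGGTTAG        9           2           1     32           0
CAAACCAG|NNNN|CTGGTTAG        8           4           1     32           0
    AACCAGTA||AACTGGTT        8           0           1      7           0
20 PQS, 0.20 per 1000 bp
```

The generator planted 25 interspersed plus 7 interleaved copies of the
20-bp imperfect palindrome, and the top-ranked form recovers exactly those
32 sites: arms of 9 bp around a 2-bp loop, one mismatch from a perfect
palindrome, none in exons. (The second row is the same 32 physical sites
read at the alternative 8-bp-arm register — spacer variants of one
family.) The AT-rich background yields the expected near-zero PQS density;
G-rich genomes score orders of magnitude higher.

The same analyses run from the shell:

```
orgscape synth --spec spec.json --seed 1 --out genome_dir/
orgscape run --genome genome.fasta --gff genome.gff3 --out report/
orgscape palindromes --genome genome.fasta --circular
orgscape pqs --genome genome.fasta --circular
```

`orgscape run` writes a deterministic bundle: composition, palindrome
ranking, motif census (whole-genome and per-gene), array list, rarity
table, six-frame profiles, phase-bias table, PQS BED + densities, dotplot
coordinates, and a JSON summary echoing every parameter.

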