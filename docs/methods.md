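# Methods

`orgscape` quantifies the repeat landscape of organellar genomes: where
imperfect palindromes and degenerate sequence motifs sit relative to the
exon/intron/intergenic partition, what their insertion into coding
sequences does to the encoded protein in terms of stop codons and codon
rarity, and how dense potential G-quadruplex-forming sequences (PQS) are.
This note records the models, conventions and numerical choices behind
each stage, and what the synthetic-genome tests do and do not demonstrate.

## Coordinates and the genome partition

All coordinates are 0-based half-open internally. GenBank and GFF3 use
1-based inclusive coordinates; conversion happens exactly once, at the I/O
boundary, which removes the usual off-by-one ambiguity when mixing the two
formats. Topology is always explicit: the GenBank LOCUS circular flag is
honoured, FASTA defaults to linear unless overridden. Circularity matters
downstream — scanners cross the origin, and a circular genome has no
artificial intergenic break at position 0.

Every base receives exactly one partition label with precedence
`exon > structural_RNA > intron > intergenic`. "Coding DNA" is defined as
exon plus structural-RNA (tRNA/rRNA) bases; introns and ORFs inside
introns are excluded from it, the convention used in comparative plastome
summary tables. Because the three-way split (coding / intron / intergenic)
is kept explicit, either convention for pooling introns into "intergenic"
can be recomputed from the same `PartitionMap`.

GFF3 is read by a small strict parser (9 columns, `ID`/`Parent`
attributes, mixed-strand genes rejected); introns are synthesized from the
gaps between consecutive CDS segments of one gene, and a gene split into
rows touching both position 0 and the sequence end on a circular genome is
reconstructed as a single origin-wrapping feature. GenBank and FASTA pass
through Biopython's `SeqIO`.

## Imperfect palindromes

An imperfect palindrome (IP) `L|S|R` consists of two arms whose reverse
complements match within a mismatch budget, separated by a spacer S (the
presumed loop of a cruciform or hairpin). Mismatches are counted on the
arms only; spacer bases are unconstrained. The default search space —
arms 8–100 bp, spacers 0–10 bp, at most one mismatch — follows the usual
palindrome-survey settings for organellar genomes; the range is read as
the **arm** length range, which matches the arm sizes such surveys report
(a total-length reading is available by configuring the arm range
accordingly).

The scanner works per center (spacer position and length): arm-pair
matches are evaluated outward from the spacer with a vectorised
mismatch-cumsum, and for each mismatch level the maximal arm is taken.
A hit is suppressed if a longer hit at the same center has no more
mismatches; a perfect shorter palindrome nested inside a longer imperfect
one is *not* suppressed, since it is a distinct structure. A site and its
reverse complement are one physical palindrome and are reported once.
These rules are mirrored by an independent brute-force enumeration oracle
(all `(center, spacer, arm)` triples tested directly) with which the
scanner agrees exactly on hundreds of random sequences; the scanner exists
because the oracle is quadratic and unusable at genome scale.

One monotonicity caveat: widening the arm range can replace a reported hit
by a longer hit at the same center (maximality), so the guarantee is
coverage — every hit under a narrower configuration is covered by a hit at
the same center under a wider one — not literal set inclusion.

Ranking groups hits by a strand-invariant canonical form (the
lexicographic minimum of the `L|S|R` form and its reverse complement),
with the spacer masked as an N-run by default so that spacer variants of
one palindrome family count together; exact-spacer grouping is available.

## Degenerate motif census

Motif patterns are fixed-length strings over IUPAC codes plus bracketed
per-position alternatives (`GCTGAC[AT]T`); `|` and spaces are cosmetic.
Because every degenerate element is per-position, a pattern is a product
of per-position base sets: reverse complementation and
self-reverse-complement detection are position-wise and never require
enumerating expansions. Matching uses overlap-permitting regular
expression lookahead in both orientations; a self-reverse-complement
pattern reports one orientation only, since the two are indistinguishable.

Hits are labelled by the partition of their start base. Gene-resident hits
report orientation relative to the *coding* strand and, for exonic hits,
the frame offset of the first coding-strand base within the spliced CDS
(mod 3) — measured on the spliced CDS, not the genome, because the
biological question is what the repeat does to the reading frame.
Variant sets may be nested (each variant naming a parent); by default a
child's hits are also counted by every ancestor, so counts are nested
categories rather than mutually exclusive bins; a mutually-exclusive mode
is a flag away. Partition-split counts are asserted to sum to the
genome-wide count on every census.

Array detection takes position-sorted hits and returns maximal runs of at
least `min_copies` hits with inter-hit gaps at most `max_gap` (defaults 3
and 20 bp — "cluster" has no canonical definition, so both are
configurable and echoed in the report). A two-motif run is called
interleaved when motif identities alternate in at least 80% of adjacent
pairs.

The shipped motif set (`motif_sets/leontynka_plastome.json`) contains the
repeat units printed in the source study's running text. Two entries are
reconstructions and are labelled as such in the config: the
perfect-palindrome core (`variant1`, the unique self-reverse-complement
form) and a 27-nt unit back-translated from its published in-frame peptide
KDKPANLTS (`variant8_reconstructed`); the study's full variant hierarchy
is defined in a figure whose machine-readable form was not available, so
the hierarchy here covers the printed motifs only.

## Codon usage, rarity categories and frame impact

Codon usage is counted over exact triplets of the spliced CDS set
(trailing partial codons dropped with a warning). Rarity categories are
built on the codons *observed* in the genome, ranked by ascending
frequency with lexicographic tie-breaks for determinism: `rareX` is the
maximal prefix of that ranking whose cumulative frequency stays strictly
below X% of all codons (X = 2, 4, 10, 20), and `common50` the minimal
suffix exceeding 50%. The categories nest by construction; stop codons are
excluded. Rare amino acids default to the two least-used ones. An
independent cumulative-sum oracle reproduces the construction on random
usage tables in the test suite.

Six-frame profiles translate a degenerate motif in frames +0/+1/+2 and, on
the reverse complement, −0/−1/−2, counting only complete in-motif codons —
boundary codons depend on genomic context and are handled per hit by the
phase-bias report instead. Because degenerate positions are independent
across the disjoint codons of a frame, the (min, max) over all expansions
of stop and rare-codon counts is the sum of per-codon minima/maxima, and
both bounds are attained by explicit expansions (verified exhaustively for
small motifs). Supplying observed genomic copies flags categories whose
theoretical maximum never occurs in practice.

The phase-bias report is deliberately descriptive — a contingency table of
coding-strand orientation against frame offset, per-hit in-frame codon
readings, stop flags, and rare-codon tallies — with no test statistic,
since the underlying claim is about avoidance patterns, not a specific
sampling model.

## G4Hunter scoring

Each base in a run of k consecutive G scores +min(k, 4); C runs score the
negative; everything else, including N (which breaks runs), scores 0.
A window (default 25 bp) qualifies when |mean score| ≥ threshold (default
1.2). Same-sign qualifying windows that share bases merge into one PQS
region; density is regions per 1000 bp of the sequence as provided. The
published density convention is ambiguous between merged regions and raw
windows, so both are always computed and reported with their mode.
Circular sequences are scored on a padded ring (8 bp of left context is
enough, since the run cap is 4) so runs and windows crossing the origin
are correct.

## Composition, circularisation, dotplots

GC is G+C over A+C+G+T, N excluded from both numerator and denominator.
The composition report recomputes all percentages directly from the
partition base counts, so coding + intron + intergenic is exactly the
genome length.

Terminal-repeat circularisation compares the first and last r bp for each
candidate r and picks the r maximising the excess of matching bases over
the random expectation (0.25 per base); this peaks at the true repeat
boundary, whereas maximising raw identity is degenerate at tiny r. The
candidate must reach a 90% identity floor (configurable), the 5' copy is
retained, and the span and identity are reported. GC is
rotation-invariant, so the choice of breakpoint does not affect the
composition statistics computed on the circularised record.

Dotplot matching indexes exact words (default 15 bp) and reports shared
word coordinates in both orientations, in self or cross mode. Two random
10-kb sequences share a 15-mer with probability ~`n² · 4⁻¹⁵` per
orientation, so a clean cross-plot is the expected null.

## The synthetic genome generator

The generator emulates the genome architecture the analyses target:
a circular (default) genome with i.i.d. background bases at a requested GC
(default 0.37, an AT-rich plastome-like background), genes assembled from
random sense codons (ATG start, TAA end) split into exons with random
intron interiors, tRNA/rRNA blocks, and planted repeats in four
arrangements (tandem, interspersed, interleaved, intra-exonic insertion).
Degenerate positions are realized uniformly at random per copy and
recorded; exonic insertions are placed between codons, in frame, with
codons drawn from a caller-supplied allowed set that excludes stops by
default — emulating the selection signature of tolerated insertions.
Everything is driven by one seed; identical spec + seed gives
byte-identical output.

Three design choices exist purely to make the manifest an unambiguous
ground truth:

* **guard flanks** — bases flanking each planted block (and the all-A
  fillers between array copies) are chosen non-complementary, so a planted
  palindrome can never extend into the background by chance (otherwise
  ~25% of copies would legitimately scan at a longer arm);
* **scrubbing** — after assembly, any occurrence of a planted motif not
  lying wholly inside planted copies is mutated away (codon-safely inside
  CDSs), so the manifest lists *all* occurrences; the expected census
  count for any pattern is then derivable from the manifest alone,
  including patterns nested inside other planted units;
* **placement clearance** — independently planted intergenic blocks keep a
  50 bp clearance from each other, so two separately planted arrangements
  cannot merge into one apparent cluster (intron-targeted clusters keep
  only a 1 bp guard margin; they are meant to be dense).

The default study-scale spec (`plastome_like_spec`) is a 100 kbp circular
genome with six genes (two intron-bearing, both strands represented) and
six directives: 25 interspersed copies of the 20-bp imperfect palindrome,
a 40-copy tandem of its 12-mer partner, a 14-copy interleaved cluster, a
20-copy 32-mer cluster inside an intron, and 4 + 2 in-frame 60-nt
composite insertions in two genes' exons.

What passing the planted-truth tests shows: the scanners, partition logic,
frame bookkeeping and array segmentation are exact on genomes whose ground
truth is fully known. What it does not show: behaviour on real repeat
populations, which have diverged copies, nested families not in the motif
set, non-i.i.d. background composition, and no clearance between repeat
families — on real data, counts depend on the motif set supplied and on
the array-gap settings, which is why every tunable is echoed into the
report header.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run on
one CPU in well under the time a code-review iteration takes: 20 seeded
100-kbp genomes for planted-truth recovery, 100–200 random sequences of
40–2000 bp for oracle equivalence, and 200–300 random usage tables for the
rarity oracle. All randomness flows from explicit seeds; the full-scale
validation against the two deposited ~0.1–0.4 Mbp organellar records runs
whenever those GenBank files are placed under `data/` (they are too large
to bundle as text fixtures).

## Known limitations

* The palindrome scanner holds an `arm_max × genome length` matrix per
  spacer (~70 MB at 100 bp arms on a 360 kbp genome); very long genomes
  would need chunking.
* Hairpin/cruciform thermodynamics, quadruplex topology classification and
  formal statistics for the phase bias are out of scope by design.
* The nested variant hierarchy beyond the printed motifs is not
  reconstructable from the available text (see the motif-set notes); users
  analysing the original records should supply their own motif JSON to
  extend it.
* Circular scanning assumes the genome is much longer than the longest
  scanned structure (extension windows wrap once).
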