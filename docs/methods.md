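# Methods

## Overview

`igloci` implements a desk-scale pipeline for annotating immunoglobulin
loci by homology and for comparing annotations across assemblies.  The
pipeline's stages are deliberately simple, fully deterministic analogues of
the tools usually run by hand (BLAST-style search, spliced-model building,
RSS curation, coverage-identity comparison), and every stage is validated
against a synthetic locus generator that plants labelled features.  This
note records the models, the tunable parameters, the numerical choices, and
what the synthetic validation does and does not establish.

## Alignment engine

Local alignment uses affine-gap Smith–Waterman over the scheme
match = +2, mismatch = −3, gap of length *L* = −5 − 2*L* (open −5, extend
−2 per gapped base).  The DP is band-compressed: row *i* stores only
diagonals *j − i* within a window, so memory and time are
O(query × band) rather than O(query × target); with a band at least as
wide as both sequences the recursion is exactly unconstrained
Smith–Waterman, which is how the full-matrix mode used in RBH scoring and
the test oracles is obtained.  IUPAC-ambiguous bases never count as a
match (conservative identity).  The inner loops are numba-compiled; a
score-only variant with two rolling rows serves the all-vs-all RBH scoring
where no traceback is needed.

Candidate loci come from exact *k*-mer seeds (default *k* = 11) hashed over
the target, found on both strands, clustered by diagonal (clusters merge
while the diagonal gap is at most one band width), and extended once per
cluster inside a trimmed target window.  One extension per cluster — not
per seed — matters for the alignment-coverage statistic below: a uniformly
90%-identical pair yields a single long alignment at 90% identity (rejected
by a 95% threshold) rather than many short high-identity fragments.

Defaults: `seed_k = 11`, `band = 32`, `score_threshold = 100` (a perfect
50-mer).  *k* = 11 keeps seeding sensitive at the ≤2% reference divergence
the pipeline is designed for (a 36-bp J segment at 2% divergence still
carries an exact 11-mer with probability ≈0.99); band 32 tolerates the
small indel load of such alignments while keeping extensions cheap.  The
threshold 100 gates V and C segments; J and D segments are shorter than
50 bp, so they use their own thresholds (`j_score_threshold = 50`,
`d_score_threshold = 26` ≈ a near-perfect 14-mer — low enough to accept an
exact short segment, high enough that a ~200-kb genome produces no random
hit).

## Two-exon gene models

V genes are leader exon + intron + V exon.  Hits of a spliced reference on
one target and strand are chained when colinear, separated by 30–10,000 bp
of genome, and by at most 5 bp of query gap.  Two numerical details proved
load-bearing:

- **Boundary creep.** A local alignment happily extends a handful of
  score-positive chance columns past a true exon boundary into the intron,
  so exon hits can *overlap* on the query (up to tens of bases, gaps
  included).  Chaining therefore tolerates query overlaps up to 48 bp and
  resolves the junction by scanning every candidate split point inside the
  overlap for an exact GT..AG intron, keeping the split that retains the
  highest combined alignment score (the displaced chance columns always
  score less than the true exon columns they conflict with).  Outside an
  overlap, donor and acceptor are shifted independently (≤5 bp, smallest
  shift first) to the nearest GT..AG; failure flags the intron
  non-canonical rather than rejecting the model.
- **Pair selection.** Candidate exon pairs are consumed greedily by
  combined score (ties: shortest intron).  Score-first prevents noise
  micro-hits from stealing a real exon; shortest-intron ties break
  paralog chimeras (a leader chained to a neighbouring gene's exon spans a
  much longer pseudo-intron than the true 80–400 bp one).

Introns longer than 150 bp are flagged `long_intron`.  Minus-strand genes
are handled by mirroring hits onto the reverse complement (both target and
query axes flip, the CIGAR reverses), chaining in the gene frame, and
mirroring back.

Overlapping gene models from different references collapse to the
single best-scoring model per locus (ties: lower start, then lexicographic
reference id).

## RSS model

The scanner works on an outward-facing 42-bp window anchored at the
segment boundary (downstream of V/D, upstream of J with the element in
reverse orientation) and enumerates every heptamer offset and spacer.
Constraints: heptamer `CACAGTG` with at most 2 mismatches and the `CAC`
start invariant; nonamer element `ACAAAAAC` (the printed vertebrate
consensus string, 8 bp) with at most 3 mismatches; spacer 12±1 or 23±1.
The best hit minimizes total mismatches, with ties broken by smaller
offset, then the 23-spacer family before the 12-family, then the spacer
closest to nominal.  These tolerances are not uniquely fixed by common
practice; they are configurable (`heptamer_max_mm`, `nonamer_max_mm`,
`spacer_tolerance`) and the tie-break order is part of the documented
contract (the test oracle enumerates independently under the same order).
Windows truncated by a sequence end are scanned as-is.

## Functionality classification

Every check runs and all failures accumulate: leader ORF (ATG start,
in-frame, no stop), V-exon frame (length mod 3 — a single-base deletion is
the canonical frameshift), internal stops, the four invariant residues,
and RSS presence.  Residues are located by global alignment of the
translated V exon to a fixed 104-residue numbering template (match +1,
mismatch −1, gap −10/−1; the strong gap penalty keeps equal-length
paralogs on the gapless diagonal).  A residue the alignment cannot map —
for example when the exon is truncated short of position 104 — fails its
check; this alignment-based rule, rather than a hard minimum exon length,
also handles the legal one-codon junction ambiguity that tandem repeats
across a splice site create.  Expression evidence never rescues a
residue-defective gene: transcribed pseudogenes exist, and coupling the
label to read depth would make it irreproducible across tissues.
J and D segments are single-exon; their functionality reduces to RSS
presence (plus a stop-free translation for J), and C genes are checked for
internal stops only.

## Locus metrics

- **Motif windows.** RGYW start positions are counted per non-overlapping
  window (default 2,500 bp) tiled from the region start; overlapping
  occurrences all count, a boundary-spanning match is credited to the
  window containing its start, and only the given strand is scanned — the
  reverse-strand mirror WRCY is a biologically distinct hotspot, so
  double-strand counting is deliberately not the default.
- **Alignment coverage (AC).** Query-relative percentage of bases covered
  by at least one local alignment with identity ≥ `ac_identity_threshold`
  (default 0.95, identity = matches / aligned columns, gaps counted).
  Alignments below the mapper's significance score are ignored, which is
  what keeps random cassette pairs at AC ≈ 0.  AC is not symmetric
  (containment gives 100 one way, less the other), so the matrix stores
  all ordered pairs; when comparing against externally reported values
  both orientations should be checked.
- **Redundancy.** Exact-match grouping of amino-acid sequences after
  upper-casing/trimming; reports counts, unique count and singletons.

## Cross-assembly RBH

Scores are full (unbanded) local alignments of gene sequences (exons only
— introns add alignment noise without information), best of both strands;
a gene with no target above the score threshold is unpaired.  (*a*, *b*)
is a pair iff each is the other's best hit, ties broken by lexicographic
id.  Unpaired counts are reported as-is; distinguishing allelic variation
from copy-number variation is interpretation, not computation.

## The synthetic locus generator

`LocusBlueprint` defaults encode the study-scale architecture: 87 V genes
(64 functional, 23 pseudogenes, all in one transcriptional orientation),
13 tandem J–C cassettes of 5 J segments, 2 orphon V genes on a separate
record with their RSS removed, RGYW-enriched switch regions upstream of C
exons, intergenic spacers of i.i.d. uniform DNA (mean 800 bp; the simplest
null for motif statistics — a plain spacer also stands in for the tRNA
cluster that splits real V arrays).  V genes derive from fixed leader and
V-domain amino-acid templates, mutated per gene at 10% of non-critical
residues and reverse-translated with random codons, which gives paralogs
~20% nucleotide divergence — enough that reference-to-paralog cross-hits
rank strictly below the true locus.  Intron lengths are drawn 80–150 bp,
or 151–400 bp with probability 0.15 so the long-intron flag is exercised
at a realistic rate.  Pseudogenes receive exactly one labelled corruption:
an internal stop, a single-base deletion, a replaced invariant residue, or
an RSS window resampled until it contains no heptamer within scanning
tolerance.  J–C cassettes are copies of one template cassette mutated at
`cassette_mutation_rate` (default 1%, a recent-duplication level of
divergence; substitutions only, so truth coordinates survive; RSS elements
are never mutated and substitutions that would create an in-frame stop are
skipped, keeping planted labels sound).  Two copies mutated independently
at rate *p* have expected identity 1 − 2*p*(1−*p*) − (2/3)*p*².  Switch
regions plant random RGYW realizations iteratively until the target count
(enrichment × length/32) is met; enrichment factors up to ~4 calibrate
exactly, larger ones saturate near the random-packing limit (~5–6×
background) — still far above any background window.  No quantitative
model of real switch-region motif density exists to copy, so the
enrichment factor (default 8) is a free synthetic parameter.  Simulated
reads give expressed genes 15–60 exon-overlapping intervals and silent
genes 0–3 (functional genes are expressed except the most distal C gene,
mirroring a transcriptionally silent terminal cassette).

Everything derives from one seeded generator: identical blueprint + seed
reproduce the genome and truth byte-for-byte.

**What passing on synthetic data shows — and what it does not.**  The
generator plants clean, template-derived genes in i.i.d. uniform
intergenic DNA.  It contains no repeat elements, no GC heterogeneity, no
CDR length variation (the numbering template is fixed, so residue
checks on real V genes with unusual CDR1/CDR2 lengths would need IMGT gap
handling), no sequencing or assembly error, and a single haplotype.
Perfect recovery here certifies the bookkeeping — coordinates, strands,
splice boundaries, labels, thresholds — not performance on a real 30-Gbp
genome, where repeat-induced spurious seeds and diverged references would
dominate the error budget.

## Evaluation and problem sizes

Annotations are scored against truth by greedy 1-to-1 overlap matching
within each segment class, requiring both boundaries within ±5 bp;
unmatched features count as false negatives/positives, matched pairs feed
a functionality confusion matrix, and J–C cassettes are re-inferred from
the annotation (a maximal run of J segments followed by a C gene) and
counted against the planted number.  RSS and switch-region features are
planted and emitted but scored separately in unit tests via attributes
rather than in the headline recall.

The shipped validation runs at the study-scale blueprint (~185 kb of
genome, 167 segments) for exact-recovery and 2%-divergence checks (ten
seeds, recall pooled), 13 cassettes for the AC matrix, 20-gene sets with
1–5 planted duplications (100 replicates) for RBH, and 100 random 10-kb
sequences / 1,100 windows for the motif and RSS oracle-equivalence checks.
These sizes keep a full validation run in a few minutes on one core while
leaving every statistic comfortably away from its decision boundary.

## Known limitations

- Alignment significance is a raw score cutoff, not an E-value; scores do
  not adapt to genome size.
- The two-exon model is specific to V genes; general multi-exon spliced
  alignment (e.g. four-exon C genes with transmembrane exons) is out of
  scope — C genes are mapped as single blocks.
- IMGT gap numbering for arbitrary CDR lengths, phylogenetic clan
  assignment, and synteny-based orthology are not implemented.
- The RBH ranking assumes Smith–Waterman scores order candidates the same
  way BLAST bit-scores would; for borderline near-ties this is plausible
  but not guaranteed.
- BED intervals stand in for read alignments; no MAPQ or multi-mapping
  logic is applied.
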