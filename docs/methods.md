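# Methods

## Objects and conventions

All coordinates are 1-based inclusive; all sequences are assumed given on the
coding strand (the GFF3 reader normalises reverse-strand annotations by
reverse-complementing the gene and flipping coordinates).  A gene model is an
ordered chain of exons per CDS; the gene structure S(g) merges *overlapping*
exons of E(g) only — abutting exons (b_i + 1 = a_j) are kept separate, since
they represent distinct splice junctions rather than one contiguous exon.
`gpos` maps a CDS coordinate to its gene coordinate by walking the exon
chain; projecting a CDS *interval* takes (gpos(start), gpos(end)), which may
span introns — downstream consumers that need exonic resolution (the MSA
derivation) re-expand the interval position by position.

A PSpA is an ordered block chain that tiles its CDS completely: conserved
blocks pair a CDS segment with a gene segment and may carry the percent
identity (PID, fraction of identical columns) of the underlying segment
alignment; deleted blocks have no gene counterpart.  PSpAs induced from an
MSpA carry no PID (the reduction records no alignment).

Multiblock consistency is classified over shared keys only: before, after,
overlaps, or inconsistent when shared keys disagree.  Multiblocks with
disjoint key sets are freely placeable ("before" by convention); the chain
position of such a candidate is fixed at assembly time.

## Baseline pairwise spliced aligner

PSpA computation is treated as an exchangeable front end; the bundled
baseline is an exon-anchored local aligner: each CDS exon is searched against
every gene-structure segment (fallback: the whole gene) with Smith–Waterman
scoring **match +2 / mismatch −3 / gap open −5 / gap extend −2**
(Bio.Align.PairwiseAligner); the best hit becomes a conserved block when its
PID ≥ **0.5** (`--min-pid`) and its coordinates extend the chain
monotonically on both sequences.  Adjacent exons matched contiguously on the
gene merge into one block, so block boundaries need not coincide with exon
boundaries.  Uncovered CDS runs become deleted blocks.  Self-alignment of a
CDS against its own gene recovers the gene model exactly at any threshold.
The aligner has no splice-signal model and no frameshift awareness; curated
or externally computed PSpAs can be supplied through the TSV format instead.

## Spliced alignment graph

Vertices are segments deduplicated by (sequence, start, end).  Every
conserved block of a CDS c (of gene g) against gene h contributes the CDS
segment, the h segment and the own-gene projection as vertices, one block
edge {CDS segment, h segment} and one CDS edge {CDS segment, projection};
when h = g the two gene segments coincide and only a CDS edge results.
Deleted blocks contribute nothing.

Edge confidence is `PID(e) * connect(e)`.  `PID(e)` comes from the PSpA
block (1.0 for CDS edges, which are exact by construction; recomputed by
global alignment when a block carries none).  `connect(e)` is the Jaccard
index of the **closed** neighbourhoods of the endpoints.  The open variant
(endpoints excluded) is identically zero on pendant edges — precisely the
shape of a spurious one-block alignment hanging off a component — which
would make every cut through such edges free and the tie-breaking arbitrary;
the closed variant is degenerate nowhere and still gives 1.0 to endpoints
sharing their whole neighbourhood.  The formula is a package choice and is
isolated in `weight_edges` so alternatives can be swapped in.

A component holding two non-overlapping segments of one sequence cannot be a
multiblock.  Conflicts are resolved pair by pair, in deterministic order
(components by decreasing size then lexicographic content), by removing a
minimum s–t cut (networkx preflow-push) under the confidence capacities;
CDS edges get effectively infinite capacity and are never removed, which also
guarantees a CDS segment is never separated from its own-gene projection.
Weights are computed once on the initial graph and kept fixed during
splitting, for determinism and simplicity.

## Greedy assembly

Post-split components become candidate multiblocks (same-sequence vertices
that still overlap are union-merged; pairwise overlap within a component
guarantees a single interval).  Candidates are sorted by decreasing key-set
size, ties broken by sorted entry lists.  Insertion into the growing chain:

* shared-key relations cleanly before/after → insert at a position
  compatible with all of them (within the admissible window the chain is
  kept sorted by the smallest entry start);
* entangled (any shared key overlapping) with exactly one existing
  multiblock → union-merge when every shared key unions to a single interval
  (overlap or abutment) and the merged chain remains valid; merging
  preserves the most pairwise-block support;
* anything else is skipped and reported.

After the sweep, uncovered CDS intervals (from deleted blocks or skipped
candidates) are patched in as {CDS segment, own-gene projection} multiblocks
through the same insertion machinery — patch runs are split at exon
boundaries so each projection is a contiguous gene interval.  Patches merge
into existing multiblocks whenever their projection overlaps one; a strict
"append" would violate the chain condition in exactly those cases.  The
result always passes the four-condition validator (enforced in tests and by
the `build` command).

The assembly greedily maximises the number of input conserved blocks
contained in multiblocks; it is a heuristic — on an adversarial candidate
set the greedy order can in principle lose to exhaustive search, which the
test suite probes on small instances.

## Derivations

**CDS MSA.**  Per multiblock, the gene segments are aligned by center-star
(center = longest segment; pairwise global alignment at match +1 /
mismatch −1 / gap −2; "once a gap, always a gap" merging).  Each CDS row
copies its own gene's row restricted to the exonic positions of its segment
— the "forced" placement — and is gapped elsewhere; multiblocks lacking a
CDS contribute gap runs.  Concatenation in chain order, reduction to the CDS
rows and removal of all-gap columns yields the family CDS alignment; every
row ungaps to its CDS sequence by construction.

**Ortholog groups.**  c1 ~ c2 (distinct genes) iff they occupy exactly the
same multiblocks and each segment pair has lengths congruent modulo 3 (same
splicing structure, same reading frame).  The relation is closed
transitively (graph connected components); singletons are kept, so the
result is a partition of C.

**Gene-model prediction.**  A source CDS projects onto a distinct target
gene when every multiblock containing the source also contains the target
gene with a mod-3 length-congruent segment.  The symmetric direction (target
gene in multiblocks without the source) is deliberately *not* required:
demanding it would forbid predicting any sub-isoform of an annotated gene
and contradicts the worked example, where the two-exon prediction on gene g
succeeds although g also occupies multiblocks with its own CDSs.  The
concatenated target segments (abutting segments merged into one exon) are
accepted when non-empty, not identical to an annotated CDS of the target,
and free of internal in-frame STOP codons (frame 1; TAA/TAG/TGA; a terminal
STOP is allowed, matching a complete CDS).  An accepted prediction is by
construction a splicing ortholog of its source.

## Evaluation

MSA precision/recall/F-score use aligned nucleotide pairs from columns where
both rows are non-gap (CDS rows only); empty pair sets score precision 1 and
F 0 when both are 0.  The Rand index is computed via
`sklearn.metrics.rand_score` on label vectors; the brute-force pair
enumeration lives in the tests as the independent oracle.  Prediction
scoring supports exact sequence identity (`strict100`) and reciprocal best
hits at global-alignment PID > 0.9 (`rbh90`), using the baseline scoring
matrix and lexicographic tie-breaking; the frameshift-aware pairwise aligner
used in some published comparisons is not reimplemented, and this standard
Needleman–Wunsch PID is a documented substitution.

## Simulator

The simulator emulates a small family evolving on a fixed species tree
(default: five leaves, unit-scale branch lengths): a root gene with 4–8
exons (lengths 30–90, multiples of 3), introns of 20–60 nt, and 1–3 root
transcripts with *distinct* exon subsets; along each branch, per-site
substitutions with probability `substitution_rate × branch length` (capped
at 0.75), optional exon skipping (default 0.1 per transcript per branch,
starting a new ortholog lineage), optional transcript loss (0.05), and
optional codon-length intron deletions (off by default).  Exon boundaries
never move and exons never gain or lose positions, so the true MSA is
column-exact over root coordinates and true splicing-ortholog groups are
exactly the ancestral-transcript lineages.  Defaults mirror a five-gene,
5–11-CDS family at toy scale; rates {0, 0.05, 0.2} span a
low/medium/high-divergence sweep.

What passing tests on simulated families do and do not show: they verify the
pipeline end to end under conserved exon boundaries and i.i.d. substitution
noise; they say nothing about exon gain/duplication, boundary shifts, coding
indels, lineage-heterogeneous rates, or real splice-signal structure — none
of which the simulator generates.

## Numerical and degenerate-input choices

Determinism everywhere: sorted iteration orders, lexicographic tie-breaks,
first-alignment selection in Biopython, seeded numpy generators.  Empty CDS
sets yield empty structures; a family with a single CDS yields a gap-free
one-row MSA and a singleton partition; predictions that would be empty are
rejected.  Problem sizes in the test and acceptance runs (20 families for
the validity sweep, 3 seeds × 3 rates for the divergence sweep) are the
package's own choice of a compact but representative regime.

## Known limitations

No trans-splicing, no genes sharing exons across loci, no UTR/intron
retention semantics, no splice-site (GT–AG) validation of predicted introns,
no protein-level annotation beyond STOP scanning, and no global optimisation
of the block-packing objective — only the greedy scheme with its documented
tie-breaks.
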