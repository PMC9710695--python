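# mspa — multiple spliced alignment of gene families

Eukaryotic genes produce alternative transcripts whose coding sequences
(CDSs) are built from overlapping subsets of exons.  Comparing the CDSs of a
gene family therefore requires alignments that respect the exon–intron
structure: a *spliced* alignment highlights homologous exon segments rather
than individual matching nucleotides.  `mspa` is a toolkit for biologists and
method developers who want to

* combine **pairwise spliced alignments** (PSpAs) — block chains aligning one
  CDS to one gene — into a single **multiple spliced alignment** (MSpA) of a
  whole family,
* derive from it a multiple CDS alignment, **splicing-ortholog groups**
  (transcripts with the same exon composition across genes), and
  **homology-predicted gene models** (putative CDSs projected onto a gene
  from its relatives' transcripts), and
* evaluate all of the above against ground truth from a bundled gene-family
  simulator.

## The model

An MSpA of CDS set *C* and gene set *G* is an ordered chain
A = A[1] … A[n] of *multiblocks*.  Each multiblock maps a subset of C ∪ G to
one segment per sequence and represents a set of homologous exon segments.
A valid chain satisfies: (1) every multiblock is non-empty, (2) per-sequence
segments strictly increase along the chain, (3) the segments of every CDS
cover it entirely, and (4) each multiblock containing a CDS also contains its
source gene, with the CDS segment's `gpos` projection (CDS coordinate → gene
coordinate) inside the gene segment.

Given PSpAs for the (CDS, gene) pairs of a family, the assembly is a greedy
multiblock algorithm on the **spliced alignment graph**: segments are
vertices; conserved PSpA blocks contribute *block edges* (cross-gene
alignments) and *CDS edges* (a CDS segment tied to its own gene's region).
Edges are weighted by percent identity `PID(e)` and a connectivity score
`connect(e)`; components containing two non-overlapping segments of one
sequence are split by removing minimum-capacity sets of low-confidence edges;
the surviving components become candidate multiblocks that are inserted, in
decreasing order of size, into a growing valid chain.

## Worked example

The package bundles a two-gene family (genes `g`, 62 nt, and `h`, 60 nt, with
CDSs `c1`/`c2` and `c3`/`c4`) plus four curated PSpAs:

```sh
mspa example --out ex
mspa build --pspas ex/pspas.tsv --genes ex/genes.fa --models ex/models.gff3 --out mspa.json
# wrote MSpA with 5 multiblocks to mspa.json (11 pairwise blocks included, 1 edges removed)
mspa orthologs --mspa mspa.json --genes ex/genes.fa --models ex/models.gff3 --out groups.tsv
# wrote 3 groups to groups.tsv
mspa predict --mspa mspa.json --genes ex/genes.fa --models ex/models.gff3 \
     --target-gene g --out-prefix pred
# predicted 1 CDS(s) on g (1 sources rejected)
cat pred.fa
# >g.pred1
# AAGCAGGTCTGGGGTGATTGA
```

What the numbers mean: the four input PSpAs carry 12 conserved blocks; the
assembled MSpA packs 11 of them into 5 multiblocks (the 12th is a deliberate
spurious low-identity block whose edge is removed during conflict
splitting).  The 3 ortholog groups are {c1, c3}, {c2}, {c4} — c1 and c3
occupy the same multiblocks with length-congruent segments (mod 3), so they
are splicing orthologs.  Projecting c4 onto gene g predicts a new two-exon
CDS `AAGCAGGTCTGG|GGTGATTGA` that ends in a stop codon and is not yet
annotated on g.

The same pipeline runs on simulated families with known truth:

```sh
mspa simulate --seed 42 --out sim
mspa pspa  --genes sim/genes.fa --models sim/models.gff3 --out sim/pspas.tsv
mspa build --pspas sim/pspas.tsv --genes sim/genes.fa --models sim/models.gff3 --out sim/mspa.json
mspa orthologs --mspa sim/mspa.json --genes sim/genes.fa --models sim/models.gff3 --out sim/groups.tsv
mspa evaluate orthologs --estimated sim/groups.tsv --truth sim/truth_groups.tsv
# {"rand_index": 1.0}
```

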