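"""Core objects of the multiple spliced alignment (MSpA) framework.

A *gene model* represents one coding sequence (CDS) of a gene as an ordered
chain of exons, i.e. 1-based inclusive intervals on the gene sequence.  The
*gene structure* S(g) merges all overlapping exons used by any CDS of g.  A
*pairwise spliced alignment* (PSpA) aligns one CDS to one gene as a chain of
blocks; a *multiple spliced alignment* (MSpA) generalises this to a chain of
multiblocks, each mapping a subset of the CDSs and genes of a family to one
segment apiece.

All coordinates are 1-based and inclusive throughout the package, so GFF3
input needs no shifting.  All sequences are assumed to be given on the coding
strand.

An MSpA must satisfy four validity conditions:

1. every multiblock is non-empty;
2. for any sequence x present in two multiblocks i1 < i2, the segment of x in
   i1 ends strictly before the segment of x in i2 starts;
3. for every CDS c, the segments of c across the chain cover c entirely;
4. every multiblock containing a CDS c of gene g also contains g, and the
   projection of c's segment onto g (via ``gpos``) lies inside g's segment.

``validate_mspa`` checks all four and reports violations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence


class MspaError(ValueError):
    """Raised on structurally invalid inputs."""


@dataclass(frozen=True, order=True)
class Segment:
    """A 1-based inclusive interval on a named sequence.

    The universal unit of exons, blocks and multiblock entries.
    """

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise MspaError(
                f"invalid segment {self.seq_id}:{self.start}-{self.end} "
                "(need 1 <= start <= end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Segment") -> bool:
        """True if the two intervals share at least one position."""
        return self.start <= other.end and other.start <= self.end

    def abuts(self, other: "Segment") -> bool:
        """True if the two intervals are adjacent without overlapping."""
        return self.end + 1 == other.start or other.end + 1 == self.start

    def union(self, other: "Segment") -> "Segment":
        """Single-interval union; requires overlap or adjacency."""
        if not (self.overlaps(other) or self.abuts(other)):
            raise MspaError(f"union of disjoint segments {self} | {other}")
        return Segment(self.seq_id, min(self.start, other.start), max(self.end, other.end))

    def contains(self, other: "Segment") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene sequence plus the exon chains of its CDSs.

    ``cds_models`` maps each CDS identifier to its ordered chain of exons on
    the gene.  Within a chain, successive exons must satisfy b_i < a_{i+1};
    exon chains of *different* CDSs may overlap freely (alternative splicing).
    """

    gene_id: str
    sequence: str
    cds_models: Mapping[str, tuple[Segment, ...]]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for cds_id, chain in self.cds_models.items():
            if not chain:
                raise MspaError(f"CDS {cds_id} has no exons")
            prev_end = 0
            for seg in chain:
                if seg.seq_id != self.gene_id:
                    raise MspaError(
                        f"exon {seg} of CDS {cds_id} is not on gene {self.gene_id}"
                    )
                if seg.start <= prev_end:
                    raise MspaError(
                        f"exons of CDS {cds_id} are not strictly increasing at {seg}"
                    )
                if seg.end > n:
                    raise MspaError(
                        f"exon {seg} of CDS {cds_id} exceeds gene length {n}"
                    )
                prev_end = seg.end

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_ids(self) -> tuple[str, ...]:
        return tuple(self.cds_models)

    def all_exons(self) -> set[Segment]:
        """E(g): the set of all exons of all CDSs of this gene."""
        exons: set[Segment] = set()
        for chain in self.cds_models.values():
            exons.update(chain)
        return exons


@dataclass(frozen=True)
class GeneStructure:
    """S(g): the ordered chain of merged, pairwise disjoint exon segments."""

    gene_id: str
    segments: tuple[Segment, ...]


def gene_structure(model: GeneModel) -> GeneStructure:
    """Merge all *overlapping* exons of E(g) into the gene structure S(g).

    Merging is by interval overlap (at least one shared position); abutting
    exons (b_i + 1 = a_j) are kept separate.
    """
    exons = sorted(model.all_exons())
    merged: list[Segment] = []
    for exon in exons:
        if merged and exon.start <= merged[-1].end:
            merged[-1] = Segment(model.gene_id, merged[-1].start, max(merged[-1].end, exon.end))
        else:
            merged.append(exon)
    return GeneStructure(model.gene_id, tuple(merged))


def cds_sequence(model: GeneModel, cds_id: str) -> tuple[str, tuple[Segment, ...]]:
    """Return g[c] and its exon chart in CDS coordinates.

    g[c] is the concatenation of the gene exon sequences composing c; the
    chart gives, for each gene exon, the corresponding interval on g[c]
    (seq_id of chart segments is the CDS id).
    """
    if cds_id not in model.cds_models:
        raise MspaError(f"unknown CDS {cds_id!r} in gene {model.gene_id}")
    parts: list[str] = []
    chart: list[Segment] = []
    pos = 0
    for exon in model.cds_models[cds_id]:
        parts.append(model.sequence[exon.start - 1 : exon.end])
        chart.append(Segment(cds_id, pos + 1, pos + exon.length))
        pos += exon.length
    return "".join(parts), tuple(chart)


def cds_length(model: GeneModel, cds_id: str) -> int:
    if cds_id not in model.cds_models:
        raise MspaError(f"unknown CDS {cds_id!r} in gene {model.gene_id}")
    return sum(e.length for e in model.cds_models[cds_id])


def gpos(model: GeneModel, cds_id: str, k: int) -> int:
    """Map CDS position k (1-based) to its position on the gene.

    Strictly increasing in k; maps each CDS exon bijectively onto its gene
    exon.
    """
    if cds_id not in model.cds_models:
        raise MspaError(f"unknown CDS {cds_id!r} in gene {model.gene_id}")
    if k < 1:
        raise MspaError(f"CDS position {k} out of range for {cds_id}")
    offset = 0
    for exon in model.cds_models[cds_id]:
        if k <= offset + exon.length:
            return exon.start + (k - offset - 1)
        offset += exon.length
    raise MspaError(f"CDS position {k} out of range for {cds_id} (length {offset})")


def project_segment(model: GeneModel, cds_id: str, segment: Segment) -> Segment:
    """Project a CDS-coordinate segment onto the gene: (gpos(s), gpos(e))."""
    return Segment(model.gene_id, gpos(model, cds_id, segment.start), gpos(model, cds_id, segment.end))


# ---------------------------------------------------------------------------
# Blocks, PSpAs, multiblocks, MSpAs


@dataclass(frozen=True)
class Block:
    """One block of a PSpA.

    Conserved blocks pair a CDS segment with a gene segment (and may carry the
    percent identity of the underlying segment alignment, as a fraction in
    [0, 1]); deleted blocks have no gene counterpart.
    """

    cds_segment: Segment
    gene_segment: Optional[Segment] = None
    pid: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_segment is None and self.pid is not None:
            raise MspaError("deleted block cannot carry a pid")
        if self.pid is not None and not 0.0 <= self.pid <= 1.0:
            raise MspaError(f"pid {self.pid} outside [0, 1]")

    @property
    def conserved(self) -> bool:
        return self.gene_segment is not None


@dataclass(frozen=True)
class PSpA:
    """A pairwise spliced alignment: an ordered block chain of one CDS vs one gene."""

    cds_id: str
    gene_id: str
    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        prev_cds = 0
        prev_gene = 0
        for block in self.blocks:
            if block.cds_segment.seq_id != self.cds_id:
                raise MspaError(f"block CDS segment {block.cds_segment} not on {self.cds_id}")
            if block.cds_segment.start <= prev_cds:
                raise MspaError(
                    f"CDS segments of {self.cds_id} vs {self.gene_id} not strictly increasing"
                )
            prev_cds = block.cds_segment.end
            if block.gene_segment is not None:
                if block.gene_segment.seq_id != self.gene_id:
                    raise MspaError(f"block gene segment {block.gene_segment} not on {self.gene_id}")
                if block.gene_segment.start <= prev_gene:
                    raise MspaError(
                        f"gene segments of {self.cds_id} vs {self.gene_id} not strictly increasing"
                    )
                prev_gene = block.gene_segment.end

    def conserved_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.conserved)

    def validate_coverage(self, cds_len: int) -> None:
        """Check that the block chain tiles the CDS [1, cds_len] without gaps."""
        pos = 1
        for block in self.blocks:
            if block.cds_segment.start != pos:
                raise MspaError(
                    f"PSpA {self.cds_id} vs {self.gene_id}: coverage gap before "
                    f"position {block.cds_segment.start} (expected {pos})"
                )
            pos = block.cds_segment.end + 1
        if pos != cds_len + 1:
            raise MspaError(
                f"PSpA {self.cds_id} vs {self.gene_id}: covers up to {pos - 1}, "
                f"CDS length is {cds_len}"
            )


class Multiblock:
    """A mapping from sequence identifiers (CDSs and genes) to segments.

    One column-group of an MSpA: a set of putatively homologous exon segments,
    at most one per sequence.
    """

    __slots__ = ("entries",)

    def __init__(self, entries: Mapping[str, Segment] | Iterable[Segment]):
        if isinstance(entries, Mapping):
            items = dict(entries)
        else:
            items = {}
            for seg in entries:
                if seg.seq_id in items:
                    raise MspaError(f"two segments for {seg.seq_id} in one multiblock")
                items[seg.seq_id] = seg
        if not items:
            raise MspaError("empty multiblock")
        for key, seg in items.items():
            if key != seg.seq_id:
                raise MspaError(f"multiblock key {key!r} does not match segment {seg}")
        self.entries: dict[str, Segment] = dict(sorted(items.items()))

    def keys(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def size(self) -> int:
        return len(self.entries)

    def __getitem__(self, seq_id: str) -> Segment:
        return self.entries[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, Multiblock) and self.entries == other.entries

    def __hash__(self) -> int:
        return hash(tuple(self.entries.items()))

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}:({s.start},{s.end})" for k, s in self.entries.items())
        return f"Multiblock({inner})"


class Relation(str, Enum):
    """Pairwise multiblock relation over shared keys."""

    BEFORE = "before"
    AFTER = "after"
    OVERLAPS = "overlaps"
    INCONSISTENT = "inconsistent"


def blocks_consistent(a: Multiblock, b: Multiblock) -> Relation:
    """Classify the relation of multiblock ``a`` to ``b`` over their shared keys.

    ``a`` is consistent with ``b`` when, for every shared sequence, a's segment
    is before b's (BEFORE), or after (AFTER), or the segments overlap
    (OVERLAPS).  Mixed relations across shared keys are INCONSISTENT.
    Multiblocks with disjoint key sets are freely placeable and classified
    BEFORE by convention.
    """
    shared = set(a.keys()) & set(b.keys())
    if not shared:
        return Relation.BEFORE
    rels = set()
    for key in shared:
        sa, sb = a[key], b[key]
        if sa.end < sb.start:
            rels.add(Relation.BEFORE)
        elif sb.end < sa.start:
            rels.add(Relation.AFTER)
        else:
            rels.add(Relation.OVERLAPS)
        if len(rels) > 1:
            return Relation.INCONSISTENT
    return rels.pop()


@dataclass(frozen=True)
class MSpA:
    """A multiple spliced alignment: an ordered chain of multiblocks."""

    cds_ids: frozenset[str]
    gene_ids: frozenset[str]
    multiblocks: tuple[Multiblock, ...]

    def __len__(self) -> int:
        return len(self.multiblocks)

    def containing(self, seq_id: str) -> tuple[int, ...]:
        """Chain indices (0-based) of multiblocks whose key set contains seq_id."""
        return tuple(i for i, mb in enumerate(self.multiblocks) if seq_id in mb)


def consistent_with_mspa(a: Multiblock, mspa: MSpA) -> bool:
    """True iff ``a`` is consistent with every multiblock of the chain and a
    strict chain position exists for it.

    A strict position requires no OVERLAPS relation (an overlapping candidate
    cannot coexist with the overlapped multiblock under condition 2) and that
    every multiblock ``a`` lies after precedes every multiblock ``a`` lies
    before in the chain.  Disjoint-key multiblocks do not constrain the
    position.
    """
    last_after = -1
    first_before = len(mspa.multiblocks)
    for i, mb in enumerate(mspa.multiblocks):
        if not set(a.keys()) & set(mb.keys()):
            continue
        rel = blocks_consistent(a, mb)
        if rel in (Relation.INCONSISTENT, Relation.OVERLAPS):
            return False
        if rel is Relation.AFTER:
            last_after = max(last_after, i)
        else:
            first_before = min(first_before, i)
    return last_after < first_before


def induce_pspa(mspa: MSpA, cds_id: str, gene_id: str) -> PSpA:
    """Reduce an MSpA to the PSpA of one CDS and one gene.

    Keeps the multiblocks containing the CDS, in chain order, and drops all
    entries except the CDS and the gene; multiblocks lacking the gene become
    deleted blocks.  Induced blocks carry no pid (the reduction records no
    alignment identity).
    """
    if cds_id not in mspa.cds_ids:
        raise MspaError(f"unknown CDS {cds_id!r} in MSpA")
    if gene_id not in mspa.gene_ids:
        raise MspaError(f"unknown gene {gene_id!r} in MSpA")
    blocks = []
    for i in mspa.containing(cds_id):
        mb = mspa.multiblocks[i]
        gene_seg = mb.entries.get(gene_id)
        blocks.append(Block(mb[cds_id], gene_seg, None))
    return PSpA(cds_id, gene_id, tuple(blocks))


@dataclass(frozen=True)
class Violation:
    """One violated MSpA validity condition."""

    condition: int
    index: Optional[int]
    seq_id: Optional[str]
    detail: str

    def __str__(self) -> str:
        where = f" multiblock {self.index}" if self.index is not None else ""
        who = f" [{self.seq_id}]" if self.seq_id else ""
        return f"condition {self.condition}{where}{who}: {self.detail}"


def cds_to_gene_map(models: Mapping[str, GeneModel]) -> dict[str, str]:
    """Map every CDS id to its source gene id; CDS ids must be family-unique."""
    out: dict[str, str] = {}
    for gene_id, model in models.items():
        for cds_id in model.cds_models:
            if cds_id in out:
                raise MspaError(f"CDS id {cds_id!r} used by two genes")
            out[cds_id] = gene_id
    return out


def validate_mspa(mspa: MSpA, models: Mapping[str, GeneModel]) -> list[Violation]:
    """Check the four MSpA validity conditions; an empty report means valid."""
    violations: list[Violation] = []
    cds_gene = cds_to_gene_map(models)

    for i, mb in enumerate(mspa.multiblocks):
        if mb.size == 0:  # unreachable through the Multiblock constructor
            violations.append(Violation(1, i, None, "empty multiblock"))

    # condition 2: per-sequence segments strictly increase along the chain
    seen: dict[str, tuple[int, Segment]] = {}
    for i, mb in enumerate(mspa.multiblocks):
        for seq_id, seg in mb.entries.items():
            if seq_id in seen:
                j, prev = seen[seq_id]
                if prev.end >= seg.start:
                    violations.append(
                        Violation(
                            2, i, seq_id,
                            f"segment ({seg.start},{seg.end}) does not start after "
                            f"({prev.start},{prev.end}) of multiblock {j}",
                        )
                    )
            seen[seq_id] = (i, seg)

    # condition 3: full coverage of every CDS
    for cds_id in sorted(mspa.cds_ids):
        gene_id = cds_gene.get(cds_id)
        if gene_id is None:
            violations.append(Violation(3, None, cds_id, "CDS not present in gene models"))
            continue
        total = cds_length(models[gene_id], cds_id)
        covered: set[int] = set()
        for i in mspa.containing(cds_id):
            seg = mspa.multiblocks[i][cds_id]
            covered.update(range(seg.start, seg.end + 1))
        missing = sorted(set(range(1, total + 1)) - covered)
        if missing:
            violations.append(
                Violation(3, None, cds_id, f"{len(missing)} uncovered positions (first: {missing[0]})")
            )

    # condition 4: CDS/gene co-membership and gpos consistency
    for i, mb in enumerate(mspa.multiblocks):
        for seq_id, seg in mb.entries.items():
            gene_id = cds_gene.get(seq_id)
            if gene_id is None:
                continue  # a gene entry
            if gene_id not in mb:
                violations.append(
                    Violation(4, i, seq_id, f"multiblock lacks source gene {gene_id}")
                )
                continue
            proj = project_segment(models[gene_id], seq_id, seg)
            if not mb[gene_id].contains(proj):
                violations.append(
                    Violation(
                        4, i, seq_id,
                        f"projection ({proj.start},{proj.end}) not inside gene segment "
                        f"({mb[gene_id].start},{mb[gene_id].end})",
                    )
                )
    return violations
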