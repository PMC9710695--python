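"""Consumers of an MSpA: multiple CDS alignment, splicing-ortholog groups and
homology-based gene-model prediction.

*Multiple CDS alignment* — an MSA is computed per multiblock (center-star over
the gene segments), every CDS row is forced onto its own gene's row through
the ``gpos`` projection, the per-multiblock alignments are concatenated in
chain order and reduced to the CDS rows.

*CDS orthology groups* — two CDSs of distinct genes are splicing orthologs
when they occupy exactly the same multiblocks and their per-multiblock
segment lengths are congruent modulo 3 (same splicing structure, same reading
frame).  The relation is closed into an equivalence and the classes are the
orthology groups.

*Gene-model prediction* — a CDS c of gene g projects onto a distinct gene h
when every multiblock containing c also contains h with a length-congruent
segment (mod 3); concatenating those h segments yields a putative CDS, kept
when it is new to h and free of internal in-frame STOP codons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from Bio import Align

from .model import (
    GeneModel,
    MSpA,
    MspaError,
    Multiblock,
    Segment,
    cds_sequence,
    cds_to_gene_map,
    gpos,
    validate_mspa,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Scoring of the per-multiblock gene-segment alignment (match, mismatch,
#: gap open, gap extend).  MSA quality inside short conserved exon blocks is
#: insensitive to this choice.
MSA_SCORING = (1.0, -1.0, -2.0, -2.0)


@dataclass(frozen=True)
class MultipleAlignment:
    """A gapped alignment: mapping sequence id -> row, all rows equal length."""

    rows: Mapping[str, str]
    n_columns: int

    def __post_init__(self) -> None:
        for seq_id, row in self.rows.items():
            if len(row) != self.n_columns:
                raise MspaError(f"row {seq_id} has {len(row)} columns, expected {self.n_columns}")

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace("-", "")

    def subset(self, seq_ids, drop_gap_columns: bool = True) -> "MultipleAlignment":
        """Restrict to a subset of rows, optionally dropping all-gap columns."""
        kept = {sid: self.rows[sid] for sid in seq_ids}
        if not drop_gap_columns or not kept:
            return MultipleAlignment(kept, self.n_columns)
        keep = [
            i for i in range(self.n_columns) if any(row[i] != "-" for row in kept.values())
        ]
        return MultipleAlignment(
            {sid: "".join(row[i] for i in keep) for sid, row in kept.items()}, len(keep)
        )


def _center_star(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star MSA: align every sequence globally to the longest one and
    merge pairwise alignments column-wise ("once a gap, always a gap")."""
    ids = sorted(seqs)
    if len(ids) == 1:
        return {ids[0]: seqs[ids[0]]}
    center = max(ids, key=lambda i: (len(seqs[i]), i))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score, aligner.mismatch_score, aligner.open_gap_score, aligner.extend_gap_score = MSA_SCORING

    center_seq = seqs[center]
    # per-sequence list of (center_position or None, char) pairs
    pairwise: dict[str, list[tuple[Optional[int], str]]] = {}
    for sid in ids:
        if sid == center:
            continue
        alignment = aligner.align(center_seq, seqs[sid])[0]
        cols: list[tuple[Optional[int], str]] = []
        ci, si = 0, 0
        a_center, a_other = str(alignment[0]), str(alignment[1])
        for ch_c, ch_o in zip(a_center, a_other):
            cpos = ci if ch_c != "-" else None
            if ch_c != "-":
                ci += 1
            if ch_o != "-":
                cols.append((cpos, ch_o))
                si += 1
            elif cpos is not None:
                cols.append((cpos, "-"))
            # ch_c == '-' and ch_o == '-' cannot occur
        pairwise[sid] = cols

    # how many insertion columns are needed before each center position
    n = len(center_seq)
    ins_before = [0] * (n + 1)
    for cols in pairwise.values():
        run = 0
        for cpos, _ in cols:
            if cpos is None:
                run += 1
            else:
                ins_before[cpos] = max(ins_before[cpos], run)
                run = 0
        ins_before[n] = max(ins_before[n], run)

    # column layout: ins_before[0] cols, center pos 0, ins_before[1] cols, ...
    offsets = [0] * (n + 1)
    total = 0
    for p in range(n + 1):
        total += ins_before[p]
        offsets[p] = total  # column index of center position p is offsets[p] + p
        # (insertions before position p are right-aligned against it)
    width = total + n

    def center_col(p: int) -> int:
        return offsets[p] + p

    rows = {center: ["-"] * width}
    for p, ch in enumerate(center_seq):
        rows[center][center_col(p)] = ch

    for sid, cols in pairwise.items():
        row = ["-"] * width
        run: list[str] = []
        for cpos, ch in cols:
            if cpos is None:
                run.append(ch)
                continue
            # place pending insertions right-aligned before this center column
            col = center_col(cpos)
            for k, ins_ch in enumerate(run):
                row[col - len(run) + k] = ins_ch
            run = []
            if ch != "-":
                row[col] = ch
        for k, ins_ch in enumerate(run):  # trailing insertions
            row[width - len(run) + k] = ins_ch
        rows[sid] = row
    return {sid: "".join(r) for sid, r in rows.items()}


def _multiblock_alignment(
    mb: Multiblock, models: Mapping[str, GeneModel], cds_gene: Mapping[str, str]
) -> dict[str, str]:
    """Align one multiblock: gene rows by center-star, CDS rows copied from
    their gene's row restricted to the gpos projection of the CDS segment."""
    gene_entries = {sid: seg for sid, seg in mb.entries.items() if sid in models}
    gene_seqs = {
        sid: models[sid].sequence[seg.start - 1 : seg.end] for sid, seg in gene_entries.items()
    }
    gene_rows = _center_star(gene_seqs) if gene_seqs else {}
    width = len(next(iter(gene_rows.values()))) if gene_rows else 0

    rows = dict(gene_rows)
    for sid, seg in mb.entries.items():
        if sid in models:
            continue
        gene_id = cds_gene[sid]
        if gene_id not in gene_rows:
            raise MspaError(f"multiblock contains CDS {sid} without its gene {gene_id}")
        model = models[gene_id]
        gene_start = gene_entries[gene_id].start
        # gene positions covered by the CDS segment (introns excluded)
        exonic = {gpos(model, sid, k) for k in range(seg.start, seg.end + 1)}
        row = []
        p = gene_start
        for ch in gene_rows[gene_id]:
            if ch == "-":
                row.append("-")
            else:
                row.append(ch if p in exonic else "-")
                p += 1
        rows[sid] = "".join(row)
    return rows


def mspa_to_cds_msa(
    mspa: MSpA, models: Mapping[str, GeneModel], *, validate: bool = True
) -> MultipleAlignment:
    """Derive the multiple CDS alignment induced by an MSpA.

    Per-multiblock alignments (gene center-star with forced CDS-on-gene
    placement) are concatenated in chain order and reduced to the CDS rows;
    all-gap columns are dropped.  Every row ungaps to its CDS sequence.
    """
    if validate:
        violations = validate_mspa(mspa, models)
        if violations:
            raise MspaError(
                "invalid MSpA: " + "; ".join(str(v) for v in violations[:5])
            )
    cds_gene = cds_to_gene_map(models)
    all_ids = sorted(mspa.cds_ids)
    parts: dict[str, list[str]] = {sid: [] for sid in all_ids}
    for mb in mspa.multiblocks:
        block_rows = _multiblock_alignment(mb, models, cds_gene)
        width = len(next(iter(block_rows.values())))
        for sid in all_ids:
            parts[sid].append(block_rows.get(sid, "-" * width))
    rows = {sid: "".join(chunks) for sid, chunks in parts.items()}
    width = len(next(iter(rows.values()))) if rows else 0
    return MultipleAlignment(rows, width).subset(all_ids, drop_gap_columns=True)


# ---------------------------------------------------------------------------
# Orthology groups


@dataclass(frozen=True)
class OrthologyPartition:
    """Disjoint CDS-id groups covering the CDS set."""

    groups: frozenset[frozenset[str]]

    def group_of(self, cds_id: str) -> frozenset[str]:
        for group in self.groups:
            if cds_id in group:
                return group
        raise KeyError(cds_id)

    def as_labels(self, order) -> list[int]:
        """Integer labels in the given element order (for metric routines)."""
        index = {}
        for i, group in enumerate(sorted(self.groups, key=lambda g: sorted(g))):
            for sid in group:
                index[sid] = i
        return [index[sid] for sid in order]


def _membership_signature(mspa: MSpA, cds_id: str) -> tuple[tuple[int, int], ...]:
    """(multiblock index, segment length mod 3) pairs for one CDS."""
    return tuple(
        (i, mspa.multiblocks[i][cds_id].length % 3) for i in mspa.containing(cds_id)
    )


def orthology_groups(mspa: MSpA, models: Mapping[str, GeneModel]) -> OrthologyPartition:
    """Infer splicing-ortholog groups from an MSpA.

    Two CDSs of distinct genes are related when they occupy exactly the same
    multiblocks with per-multiblock lengths congruent modulo 3; groups are the
    equivalence classes of the reflexive-symmetric-transitive closure.
    """
    import networkx as nx

    cds_gene = cds_to_gene_map(models)
    ids = sorted(mspa.cds_ids)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    signatures = {sid: _membership_signature(mspa, sid) for sid in ids}
    for i, c1 in enumerate(ids):
        for c2 in ids[i + 1 :]:
            if cds_gene[c1] == cds_gene[c2]:
                continue
            if signatures[c1] == signatures[c2]:
                graph.add_edge(c1, c2)
    groups = frozenset(frozenset(c) for c in nx.connected_components(graph))
    return OrthologyPartition(groups)


# ---------------------------------------------------------------------------
# Gene-model prediction


class PredictionRejected(MspaError):
    """A homology prediction failed one of its admissibility conditions."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class PredictedCDS:
    """A CDS predicted on a target gene by homology with a source CDS."""

    gene_id: str
    exons: tuple[Segment, ...]
    sequence: str
    source_cds_id: str


def _has_internal_stop(sequence: str) -> bool:
    """Scan codons in frame 1; a terminal STOP is allowed."""
    for i in range(0, len(sequence) - 2, 3):
        codon = sequence[i : i + 3]
        if codon in STOP_CODONS and i + 3 < len(sequence):
            return True
    return False


def predict_cds(
    mspa: MSpA,
    source_cds: str,
    target_gene: str,
    models: Mapping[str, GeneModel],
) -> PredictedCDS:
    """Predict a putative CDS for ``target_gene`` by homology with ``source_cds``.

    Every multiblock containing the source CDS must contain the target gene
    with a segment whose length is congruent to the source segment's modulo 3;
    the prediction concatenates those target-gene segments in chain order
    (abutting segments merge into one exon).  Raises
    :class:`PredictionRejected` when a condition fails, when the sequence
    already is a CDS of the target gene, or when it contains an internal
    in-frame STOP codon.
    """
    cds_gene = cds_to_gene_map(models)
    if source_cds not in cds_gene:
        raise MspaError(f"unknown CDS {source_cds!r}")
    if target_gene not in models:
        raise MspaError(f"unknown gene {target_gene!r}")
    if cds_gene[source_cds] == target_gene:
        raise MspaError("target gene must differ from the source CDS's gene")

    indices = mspa.containing(source_cds)
    if not indices:
        raise PredictionRejected(f"{source_cds} occupies no multiblock")
    segments: list[Segment] = []
    for i in indices:
        mb = mspa.multiblocks[i]
        if target_gene not in mb:
            raise PredictionRejected(
                f"multiblock {i} contains {source_cds} but not {target_gene}"
            )
        src_len = mb[source_cds].length
        tgt_seg = mb[target_gene]
        if (src_len - tgt_seg.length) % 3 != 0:
            raise PredictionRejected(
                f"multiblock {i}: segment lengths {src_len} and {tgt_seg.length} "
                "not congruent modulo 3"
            )
        segments.append(tgt_seg)

    exons: list[Segment] = []
    for seg in segments:  # merge abutting segments into single exons
        if exons and exons[-1].end + 1 == seg.start:
            exons[-1] = exons[-1].union(seg)
        else:
            exons.append(seg)
    target = models[target_gene]
    sequence = "".join(target.sequence[e.start - 1 : e.end] for e in exons)
    if not sequence:
        raise PredictionRejected("empty prediction")
    for cds_id in target.cds_ids():
        if cds_sequence(target, cds_id)[0] == sequence:
            raise PredictionRejected(f"prediction equals existing CDS {cds_id}")
    if _has_internal_stop(sequence):
        raise PredictionRejected("internal in-frame STOP codon")
    return PredictedCDS(target_gene, tuple(exons), sequence, source_cds)


def predict_all(
    mspa: MSpA, target_gene: str, models: Mapping[str, GeneModel]
) -> tuple[list[PredictedCDS], dict[str, str]]:
    """Run ``predict_cds`` from every foreign CDS onto one target gene.

    Returns accepted predictions (deduplicated by sequence) and a mapping of
    rejected source CDS ids to the rejection reason.
    """
    cds_gene = cds_to_gene_map(models)
    accepted: list[PredictedCDS] = []
    seen: set[str] = set()
    rejected: dict[str, str] = {}
    for cds_id in sorted(mspa.cds_ids):
        if cds_gene[cds_id] == target_gene:
            continue
        try:
            pred = predict_cds(mspa, cds_id, target_gene, models)
        except PredictionRejected as exc:
            rejected[cds_id] = exc.reason
            continue
        if pred.sequence not in seen:
            seen.add(pred.sequence)
            accepted.append(pred)
    return accepted, rejected
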