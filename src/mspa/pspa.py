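"""Pairwise spliced alignments (PSpAs): block-chain I/O and a baseline aligner.

The multiblock assembly consumes a set of PSpAs, one per (CDS, gene) pair of
the family.  This module provides a TSV reader/writer for the block-chain
format and a baseline exon-anchored pairwise spliced aligner: each CDS exon is
searched against the target gene's structure segments (and, as a fallback, the
whole gene) by local alignment, and matches above a percent-identity threshold
become conserved blocks.

The baseline aligner is a simple stand-in for dedicated spliced aligners: it
is exact for self-alignments and for families with conserved exon boundaries,
which is what the multiblock assembly needs as input.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

from Bio import Align

from .model import (
    Block,
    GeneModel,
    MspaError,
    PSpA,
    Segment,
    cds_length,
    cds_sequence,
    cds_to_gene_map,
    gene_structure,
)

#: Baseline alignment scoring (match, mismatch, gap open, gap extend).
DEFAULT_SCORING = (2.0, -3.0, -5.0, -2.0)

#: Minimum percent identity (fraction) for a local match to become a
#: conserved block.
DEFAULT_MIN_PID = 0.5

TSV_COLUMNS = ("cds_id", "gene_id", "block_index", "cds_start", "cds_end",
               "gene_start", "gene_end", "pid")


@dataclass
class PSpASet:
    """A collection of PSpAs keyed by (cds_id, gene_id)."""

    pspas: dict[tuple[str, str], PSpA] = field(default_factory=dict)

    def add(self, pspa: PSpA) -> None:
        self.pspas[(pspa.cds_id, pspa.gene_id)] = pspa

    def __getitem__(self, key: tuple[str, str]) -> PSpA:
        return self.pspas[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.pspas

    def __len__(self) -> int:
        return len(self.pspas)

    def __iter__(self):
        return iter(self.pspas.values())

    def validate(self, models: Mapping[str, GeneModel]) -> None:
        """Re-validate block chains and CDS coverage against gene models."""
        cds_gene = cds_to_gene_map(models)
        for (cds_id, gene_id), pspa in self.pspas.items():
            if cds_id not in cds_gene:
                raise MspaError(f"PSpA references unknown CDS {cds_id!r}")
            if gene_id not in models:
                raise MspaError(f"PSpA references unknown gene {gene_id!r}")
            pspa.validate_coverage(cds_length(models[cds_gene[cds_id]], cds_id))

    def fill_missing(self, models: Mapping[str, GeneModel]) -> list[tuple[str, str]]:
        """Complete the set over C x G with deletion-only PSpAs; return the
        filled pairs."""
        cds_gene = cds_to_gene_map(models)
        filled = []
        for cds_id, source_gene in cds_gene.items():
            for gene_id in models:
                if (cds_id, gene_id) in self.pspas:
                    continue
                total = cds_length(models[source_gene], cds_id)
                self.add(PSpA(cds_id, gene_id, (Block(Segment(cds_id, 1, total)),)))
                filled.append((cds_id, gene_id))
        return filled


def write_pspa_set(pspa_set: PSpASet, path) -> None:
    """Write a PSpASet as TSV (one row per block, empty gene columns for
    deleted blocks)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for key in sorted(pspa_set.pspas):
            pspa = pspa_set.pspas[key]
            for i, block in enumerate(pspa.blocks, start=1):
                if block.conserved:
                    gene_start = block.gene_segment.start
                    gene_end = block.gene_segment.end
                    pid = "" if block.pid is None else repr(block.pid)
                else:
                    gene_start = gene_end = pid = ""
                writer.writerow(
                    [pspa.cds_id, pspa.gene_id, i,
                     block.cds_segment.start, block.cds_segment.end,
                     gene_start, gene_end, pid]
                )


def read_pspa_set(path, models: Optional[Mapping[str, GeneModel]] = None) -> PSpASet:
    """Read a PSpASet from TSV; blocks are re-validated on read.

    When gene models are supplied, chains are checked for full CDS coverage
    and missing (CDS, gene) pairs are filled with deletion-only PSpAs (with a
    warning), so the returned set is complete over C x G.
    """
    rows: dict[tuple[str, str], list[tuple[int, Block]]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != TSV_COLUMNS:
            raise MspaError(f"malformed PSpA TSV header in {path}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(TSV_COLUMNS):
                raise MspaError(f"{path}:{lineno}: expected {len(TSV_COLUMNS)} columns")
            cds_id, gene_id, idx, cs, ce, gs, ge, pid = row
            try:
                block_index = int(idx)
                cds_seg = Segment(cds_id, int(cs), int(ce))
                if gs or ge:
                    gene_seg = Segment(gene_id, int(gs), int(ge))
                    pid_val = float(pid) if pid != "" else None
                else:
                    gene_seg, pid_val = None, None
                    if pid != "":
                        raise MspaError("deleted block with pid")
            except (ValueError, MspaError) as exc:
                raise MspaError(f"{path}:{lineno}: malformed row ({exc})") from exc
            rows.setdefault((cds_id, gene_id), []).append((block_index, Block(cds_seg, gene_seg, pid_val)))

    pspa_set = PSpASet()
    for (cds_id, gene_id), blocks in rows.items():
        blocks.sort(key=lambda item: item[0])
        pspa_set.add(PSpA(cds_id, gene_id, tuple(b for _, b in blocks)))
    if models is not None:
        pspa_set.validate(models)
        filled = pspa_set.fill_missing(models)
        if filled:
            warnings.warn(
                f"{len(filled)} missing (CDS, gene) pairs filled with deletion-only PSpAs",
                stacklevel=2,
            )
    return pspa_set


# ---------------------------------------------------------------------------
# Baseline pairwise spliced aligner


def _make_aligner(mode: str, scoring=DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def alignment_pid(alignment) -> float:
    """Percent identity of a Bio.Align alignment: matches / alignment columns."""
    counts = alignment.counts()
    columns = alignment.length
    if columns == 0:
        return 0.0
    return counts.identities / columns


def global_pid(a: str, b: str, scoring=DEFAULT_SCORING) -> float:
    """PID of the best global (Needleman-Wunsch) alignment of two sequences."""
    if not a or not b:
        return 0.0
    aligner = _make_aligner("global", scoring)
    return alignment_pid(aligner.align(a, b)[0])


def _best_local_match(
    aligner: Align.PairwiseAligner, query: str, target_seq: str, target_offset: int
) -> Optional[tuple[float, int, int, int, int, float]]:
    """Best local alignment of query within a target window.

    Returns (score, q_start, q_end, t_start, t_end, pid) with 1-based
    inclusive coordinates, target coordinates shifted by ``target_offset``.
    """
    if not query or not target_seq:
        return None
    alignments = aligner.align(query, target_seq)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    best = alignments[0]
    q_span = best.aligned[0]
    t_span = best.aligned[1]
    if len(q_span) == 0:
        return None
    q_start, q_end = int(q_span[0][0]) + 1, int(q_span[-1][1])
    t_start, t_end = int(t_span[0][0]) + 1, int(t_span[-1][1])
    return (
        float(best.score),
        q_start,
        q_end,
        target_offset + t_start,
        target_offset + t_end,
        alignment_pid(best),
    )


def align_pair(
    cds_seq: str,
    cds_chart: tuple[Segment, ...],
    gene: GeneModel,
    *,
    min_pid: float = DEFAULT_MIN_PID,
    scoring=DEFAULT_SCORING,
) -> PSpA:
    """Compute a baseline PSpA of one CDS against one gene.

    For each CDS exon, the gene's structure segments are searched for the
    best-scoring local alignment (falling back to the whole gene when no
    segment scores); a match above ``min_pid`` whose gene coordinates extend
    the chain becomes a conserved block, everything else a deleted block.
    Adjacent exons matched contiguously on the gene are merged into one block.
    """
    if not cds_seq:
        raise MspaError("empty CDS sequence")
    cds_id = cds_chart[0].seq_id
    aligner = _make_aligner("local", scoring)
    structure = gene_structure(gene).segments

    conserved: list[Block] = []  # strictly increasing on both coordinates
    for exon in cds_chart:
        exon_seq = cds_seq[exon.start - 1 : exon.end]
        windows = [
            (gene.sequence[seg.start - 1 : seg.end], seg.start - 1) for seg in structure
        ]
        if not windows:
            windows = [(gene.sequence, 0)]
        best = None
        for window_seq, offset in windows:
            hit = _best_local_match(aligner, exon_seq, window_seq, offset)
            if hit is None:
                continue
            if best is None or hit[0] > best[0]:
                best = hit
        if best is None and structure:
            best = _best_local_match(aligner, exon_seq, gene.sequence, 0)
        if best is None:
            continue
        score, q_start, q_end, t_start, t_end, pid = best
        if pid < min_pid:
            continue
        cds_seg = Segment(cds_id, exon.start + q_start - 1, exon.start + q_end - 1)
        gene_seg = Segment(gene.gene_id, t_start, t_end)
        if conserved:
            prev = conserved[-1]
            if gene_seg.start <= prev.gene_segment.end or cds_seg.start <= prev.cds_segment.end:
                continue  # would break chain monotonicity; treat as unaligned
        if (
            conserved
            and conserved[-1].cds_segment.end + 1 == cds_seg.start
            and conserved[-1].gene_segment.end + 1 == gene_seg.start
        ):
            # contiguous on both sequences: merge into one block
            prev = conserved.pop()
            total_cols = prev.cds_segment.length + cds_seg.length
            merged_pid = (
                prev.pid * prev.cds_segment.length + pid * cds_seg.length
            ) / total_cols
            cds_seg = prev.cds_segment.union(cds_seg)
            gene_seg = prev.gene_segment.union(gene_seg)
            pid = merged_pid
        conserved.append(Block(cds_seg, gene_seg, round(pid, 6)))

    # fill uncovered CDS runs with deleted blocks so the chain tiles the CDS
    blocks: list[Block] = []
    pos = 1
    total = len(cds_seq)
    for block in conserved:
        if block.cds_segment.start > pos:
            blocks.append(Block(Segment(cds_id, pos, block.cds_segment.start - 1)))
        blocks.append(block)
        pos = block.cds_segment.end + 1
    if pos <= total:
        blocks.append(Block(Segment(cds_id, pos, total)))
    return PSpA(cds_id, gene.gene_id, tuple(blocks))


def build_pspa_set(
    models: Mapping[str, GeneModel],
    *,
    min_pid: float = DEFAULT_MIN_PID,
    scoring=DEFAULT_SCORING,
) -> PSpASet:
    """Align every CDS of the family against every gene (complete over C x G)."""
    pspa_set = PSpASet()
    for gene_id in sorted(models):
        model = models[gene_id]
        for cds_id in model.cds_ids():
            seq, chart = cds_sequence(model, cds_id)
            for target_id in sorted(models):
                pspa_set.add(
                    align_pair(seq, chart, models[target_id], min_pid=min_pid, scoring=scoring)
                )
    return pspa_set
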