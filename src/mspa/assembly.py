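"""Greedy multiblock assembly of an MSpA from a conditioned alignment graph.

The connected components of the conflict-free graph are candidate
multiblocks.  Candidates are sorted by decreasing size (a large candidate is
supported by many pairwise blocks and is unlikely to be an artifact) and
inserted one by one into a growing chain:

* a candidate whose shared-key relations to the chain are cleanly
  before/after is inserted at a compatible chain position;
* a candidate entangled (overlapping) with exactly one existing multiblock is
  union-merged into it when every shared key unions to a single interval and
  the merged chain stays valid;
* anything else is skipped (and reported).

After the sweep, every CDS interval still uncovered (e.g. from deleted
blocks) is patched in as a {CDS segment, own-gene projection} multiblock
through the same insertion machinery, so that the chain satisfies the
coverage and gene-consistency conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx

from .model import (
    GeneModel,
    MSpA,
    MspaError,
    Multiblock,
    Relation,
    Segment,
    blocks_consistent,
    cds_length,
    cds_to_gene_map,
    project_segment,
)
from .pspa import PSpASet


@dataclass(frozen=True)
class Candidate:
    """A candidate multiblock with its provenance (component id)."""

    multiblock: Multiblock
    component: int

    @property
    def size(self) -> int:
        return self.multiblock.size


def _entry_key(mb: Multiblock) -> tuple:
    return tuple(
        (seg.seq_id, seg.start, seg.end) for seg in sorted(mb.entries.values())
    )


def components_to_candidates(graph: nx.Graph) -> list[Candidate]:
    """One candidate per connected component, sorted by decreasing size.

    Overlapping same-sequence segments inside a component (tolerated by the
    splitting stage) are union-merged, so every candidate holds at most one
    segment per sequence.  Ties in size are broken by the sorted entry list
    for determinism.
    """
    raw: list[Multiblock] = []
    for comp in nx.connected_components(graph):
        merged: dict[str, Segment] = {}
        for seg in sorted(comp):
            if seg.seq_id in merged:
                merged[seg.seq_id] = merged[seg.seq_id].union(seg)
            else:
                merged[seg.seq_id] = seg
        raw.append(Multiblock(merged))
    raw.sort(key=lambda mb: (-mb.size, _entry_key(mb)))
    return [Candidate(mb, i + 1) for i, mb in enumerate(raw)]


def _chain_valid(chain: list[Multiblock]) -> bool:
    """Condition-2 check: shared-key segments strictly increase along the chain."""
    last: dict[str, Segment] = {}
    for mb in chain:
        for seq_id, seg in mb.entries.items():
            if seq_id in last and last[seq_id].end >= seg.start:
                return False
            last[seq_id] = seg
    return True


def _try_union(a: Multiblock, b: Multiblock) -> Optional[Multiblock]:
    """Union-merge two multiblocks; None when any shared key cannot union to a
    single interval."""
    merged = dict(a.entries)
    for seq_id, seg in b.entries.items():
        if seq_id in merged:
            cur = merged[seq_id]
            if not (cur.overlaps(seg) or cur.abuts(seg)):
                return None
            merged[seq_id] = cur.union(seg)
        else:
            merged[seq_id] = seg
    return Multiblock(merged)


def _position_key(mb: Multiblock) -> tuple:
    """Canonical chain-sorting coordinate: smallest start among entries,
    preferring gene-side determinism via plain (start, seq_id) ordering."""
    return min((seg.start, seg.seq_id) for seg in mb.entries.values())


class _ChainBuilder:
    def __init__(self) -> None:
        self.chain: list[Multiblock] = []
        self.skipped: list[Multiblock] = []

    def insert(self, mb: Multiblock) -> bool:
        """Insert or merge one multiblock; returns False when it was skipped."""
        entangled: list[int] = []
        last_after = -1
        first_before = len(self.chain)
        constrained = False
        for i, existing in enumerate(self.chain):
            if not set(mb.keys()) & set(existing.keys()):
                continue
            rel = blocks_consistent(mb, existing)
            if rel is Relation.AFTER:
                constrained = True
                last_after = max(last_after, i)
            elif rel is Relation.BEFORE:
                constrained = True
                first_before = min(first_before, i)
            else:  # OVERLAPS or INCONSISTENT: try to merge
                entangled.append(i)

        if entangled:
            if len(entangled) > 1:
                self.skipped.append(mb)
                return False
            i = entangled[0]
            merged = _try_union(self.chain[i], mb)
            if merged is None:
                self.skipped.append(mb)
                return False
            trial = self.chain[:i] + [merged] + self.chain[i + 1 :]
            if not _chain_valid(trial):
                self.skipped.append(mb)
                return False
            self.chain = trial
            return True

        lo, hi = last_after + 1, first_before
        if lo > hi:
            self.skipped.append(mb)
            return False
        if not constrained:
            lo, hi = 0, len(self.chain)
        # keep the chain sorted by the canonical coordinate within the
        # admissible window
        pos = lo
        key = _position_key(mb)
        while pos < hi and _position_key(self.chain[pos]) <= key:
            pos += 1
        trial = self.chain[:pos] + [mb] + self.chain[pos:]
        if not _chain_valid(trial):
            self.skipped.append(mb)
            return False
        self.chain = trial
        return True


def _uncovered_runs(chain: list[Multiblock], cds_id: str, total: int) -> list[tuple[int, int]]:
    covered = [False] * (total + 1)
    for mb in chain:
        if cds_id in mb:
            seg = mb[cds_id]
            for p in range(seg.start, seg.end + 1):
                covered[p] = True
    runs = []
    pos = 1
    while pos <= total:
        if not covered[pos]:
            start = pos
            while pos <= total and not covered[pos]:
                pos += 1
            runs.append((start, pos - 1))
        else:
            pos += 1
    return runs


def _split_run_at_exons(run: tuple[int, int], chart: tuple[Segment, ...]) -> list[tuple[int, int]]:
    """Split an uncovered CDS run at exon boundaries so each piece projects to
    a contiguous gene interval."""
    pieces = []
    for exon in chart:
        lo = max(run[0], exon.start)
        hi = min(run[1], exon.end)
        if lo <= hi:
            pieces.append((lo, hi))
    return pieces


def assemble(
    candidates: list[Candidate],
    models: Mapping[str, GeneModel],
) -> tuple[MSpA, list[Multiblock]]:
    """Greedy size-ordered assembly of candidate multiblocks into an MSpA.

    Returns the MSpA and the list of skipped candidates (silently skipped
    during the sweep, surfaced here for logging).
    """
    from .model import cds_sequence

    cds_gene = cds_to_gene_map(models)
    builder = _ChainBuilder()
    for cand in candidates:
        builder.insert(cand.multiblock)

    # restore full CDS coverage (deleted blocks / skipped candidates)
    for cds_id in sorted(cds_gene):
        gene_id = cds_gene[cds_id]
        model = models[gene_id]
        total = cds_length(model, cds_id)
        _, chart = cds_sequence(model, cds_id)
        for run in _uncovered_runs(builder.chain, cds_id, total):
            for lo, hi in _split_run_at_exons(run, chart):
                seg = Segment(cds_id, lo, hi)
                patch = Multiblock({cds_id: seg, gene_id: project_segment(model, cds_id, seg)})
                builder.insert(patch)

    mspa = MSpA(
        cds_ids=frozenset(cds_gene),
        gene_ids=frozenset(models),
        multiblocks=tuple(builder.chain),
    )
    return mspa, builder.skipped


def included_block_count(pspa_set: PSpASet, mspa: MSpA) -> int:
    """Number of conserved PSpA blocks included in multiblocks of the MSpA.

    A block is included when some multiblock simultaneously contains its CDS
    segment (within the CDS entry) and its gene segment (within the gene
    entry).  This is the objective the greedy assembly heuristically
    maximises.
    """
    count = 0
    for pspa in pspa_set:
        for block in pspa.conserved_blocks():
            for mb in mspa.multiblocks:
                if (
                    pspa.cds_id in mb
                    and pspa.gene_id in mb
                    and mb[pspa.cds_id].contains(block.cds_segment)
                    and mb[pspa.gene_id].contains(block.gene_segment)
                ):
                    count += 1
                    break
    return count


def build_mspa(
    pspa_set: PSpASet, models: Mapping[str, GeneModel]
) -> tuple[MSpA, dict]:
    """Full pipeline: graph build, weighting, conflict splitting, assembly.

    Returns the MSpA and a report dict (removed edges, skipped candidates,
    component count).
    """
    from .graph import build_graph, split_components, weight_edges

    graph = weight_edges(build_graph(pspa_set, models))
    conditioned, removed = split_components(graph)
    candidates = components_to_candidates(conditioned)
    mspa, skipped = assemble(candidates, models)
    report = {
        "n_components": len(candidates),
        "removed_edges": removed,
        "skipped_candidates": skipped,
        "included_blocks": included_block_count(pspa_set, mspa),
    }
    return mspa, report
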