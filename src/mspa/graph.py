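"""The spliced alignment graph and its conflict-driven conditioning.

Vertices are CDS and gene segments; every conserved block of every PSpA of a
CDS c (of gene g) against a gene h contributes

* the CDS segment, the aligned segment of h, and the projection of the CDS
  segment onto its own gene g (via ``gpos``) as vertices,
* a *block edge* between the CDS segment and the h segment, and
* a *CDS edge* between the CDS segment and its own-gene projection.

When h = g the two gene segments coincide and the block induces a single CDS
edge.  Deleted blocks contribute nothing.

Each edge carries two confidence scores: ``pid``, the percent identity of the
pairwise segment alignment it represents (1.0 for CDS edges, which are exact
by construction), and ``connect``, the Jaccard index of the closed
neighbourhoods of its endpoints, a standard proxy for the strength of the
connectivity between two vertices.  Closed neighbourhoods (endpoints
included) are used because the open variant is identically zero on pendant
edges, which would make every cut through them free and the conflict
splitting degenerate.

A connected component that contains two non-overlapping segments of the same
sequence cannot become a multiblock; such conflicts are resolved by removing
a minimum-capacity set of low-confidence edges (capacity = pid * connect;
CDS edges are never removed) between each conflicting pair.
"""

from __future__ import annotations

import csv
import itertools
from typing import Iterable, Mapping

import networkx as nx

from .model import GeneModel, MspaError, Segment, cds_to_gene_map, project_segment
from .pspa import PSpASet, global_pid

BLOCK_EDGE = "block_edge"
CDS_EDGE = "cds_edge"

#: Effective capacity of edges that must never be cut.
_UNCUTTABLE = 1.0e9


def _segment_sequence(seg: Segment, models: Mapping[str, GeneModel],
                      cds_cache: dict[str, str]) -> str:
    if seg.seq_id in models:
        return models[seg.seq_id].sequence[seg.start - 1 : seg.end]
    return cds_cache[seg.seq_id][seg.start - 1 : seg.end]


def build_graph(pspa_set: PSpASet, models: Mapping[str, GeneModel]) -> nx.Graph:
    """Construct graph(X) from a set of PSpAs.

    Edge attributes: ``kind`` (block_edge / cds_edge) and ``pid``.  When the
    same vertex pair is induced by several blocks, the highest pid is kept.
    Missing block pids are recomputed from the segment sequences by global
    alignment.
    """
    from .model import cds_sequence  # local import to avoid cycle at module load

    cds_gene = cds_to_gene_map(models)
    cds_cache = {
        cds_id: cds_sequence(models[gene_id], cds_id)[0]
        for cds_id, gene_id in cds_gene.items()
    }
    graph = nx.Graph()

    def add_edge(u: Segment, v: Segment, kind: str, pid: float) -> None:
        if graph.has_edge(u, v):
            data = graph.edges[u, v]
            data["pid"] = max(data["pid"], pid)
            if kind == CDS_EDGE:
                data["kind"] = CDS_EDGE  # exactness dominates
            return
        graph.add_edge(u, v, kind=kind, pid=pid)

    for key in sorted(pspa_set.pspas):
        pspa = pspa_set.pspas[key]
        cds_id, target_gene = pspa.cds_id, pspa.gene_id
        source_gene = cds_gene.get(cds_id)
        if source_gene is None:
            raise MspaError(f"PSpA references CDS {cds_id!r} absent from gene models")
        model = models[source_gene]
        for block in pspa.conserved_blocks():
            proj = project_segment(model, cds_id, block.cds_segment)
            pid = block.pid
            if pid is None:
                pid = global_pid(
                    _segment_sequence(block.cds_segment, models, cds_cache),
                    _segment_sequence(block.gene_segment, models, cds_cache),
                )
            if target_gene == source_gene:
                # degenerate case: the aligned gene segment is the projection
                add_edge(block.cds_segment, proj, CDS_EDGE, 1.0)
            else:
                add_edge(block.cds_segment, block.gene_segment, BLOCK_EDGE, pid)
                add_edge(block.cds_segment, proj, CDS_EDGE, 1.0)
    return graph


def weight_edges(graph: nx.Graph) -> nx.Graph:
    """Assign ``connect`` (closed-neighbourhood Jaccard) to every edge in place.

    CDS edges get pid 1.0 at construction time; this pass only adds connect.
    """
    for u, v, data in graph.edges(data=True):
        nu = set(graph[u]) | {u}
        nv = set(graph[v]) | {v}
        data["connect"] = len(nu & nv) / len(nu | nv)
    return graph


def _sorted_components(graph: nx.Graph) -> list[list[Segment]]:
    comps = [sorted(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def find_conflicts(graph: nx.Graph) -> list[tuple[tuple[Segment, ...], tuple[Segment, Segment]]]:
    """All unordered pairs of same-sequence, non-overlapping vertices that
    share a connected component.

    Returns (component vertices, (u, v)) records in deterministic order.
    """
    out = []
    for comp in _sorted_components(graph):
        by_seq: dict[str, list[Segment]] = {}
        for seg in comp:
            by_seq.setdefault(seg.seq_id, []).append(seg)
        for segs in by_seq.values():
            for u, v in itertools.combinations(sorted(segs), 2):
                if not u.overlaps(v):
                    out.append((tuple(comp), (u, v)))
    return out


def split_components(graph: nx.Graph) -> tuple[nx.Graph, list[tuple[Segment, Segment, dict]]]:
    """Remove minimum-capacity cuts until no component holds a conflict.

    Capacity of a block edge is pid * connect; CDS edges are effectively
    uncuttable.  Conflicting pairs are resolved one at a time in deterministic
    order.  Returns the conditioned graph and the list of removed edges.
    """
    if graph.number_of_edges() and "connect" not in next(iter(graph.edges(data=True)))[2]:
        weight_edges(graph)
    work = graph.copy()
    for _, _, data in work.edges(data=True):
        if data["kind"] == CDS_EDGE:
            data["capacity"] = _UNCUTTABLE
        else:
            data["capacity"] = data["pid"] * data["connect"]

    removed: list[tuple[Segment, Segment, dict]] = []
    while True:
        conflicts = find_conflicts(work)
        if not conflicts:
            break
        _, (u, v) = conflicts[0]
        cut_value, (side_u, _) = nx.minimum_cut(work, u, v, capacity="capacity")
        if cut_value >= _UNCUTTABLE:
            raise MspaError(
                f"conflict between {u} and {v} is joined only by uncuttable CDS edges"
            )
        cutset = [
            (a, b)
            for a, b in work.edges()
            if (a in side_u) != (b in side_u)
        ]
        for a, b in cutset:
            removed.append((a, b, dict(work.edges[a, b])))
            work.remove_edge(a, b)
    return work, removed


def write_graph_tsv(graph: nx.Graph, path) -> None:
    """Debug dump: one edge per row with kind, pid, connect and component label."""
    labels: dict[Segment, int] = {}
    for i, comp in enumerate(_sorted_components(graph), start=1):
        for seg in comp:
            labels[seg] = i
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["u_seq", "u_start", "u_end", "v_seq", "v_start", "v_end",
             "kind", "pid", "connect", "component"]
        )
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1])):
            writer.writerow(
                [u.seq_id, u.start, u.end, v.seq_id, v.start, v.end,
                 data["kind"], f"{data['pid']:.6g}",
                 f"{data.get('connect', float('nan')):.6g}", labels[u]]
            )
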