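"""A small two-gene worked example exercising every stage of the pipeline.

The family consists of two genes, ``g`` (62 nt, CDSs c1 and c2) and ``h``
(60 nt, CDSs c3 and c4), with a shared four-region exon architecture, plus
four hand-curated pairwise spliced alignments (W: c3 vs g, X: c4 vs g,
Y: c1 vs h, Z: c2 vs h).  Y deliberately contains one spurious low-identity
block (c1:(1,4) against h:(1,4), PID 0.5) whose removal during conflict
splitting is part of the scenario, and Z starts with a deleted block (c2's
first exon has no counterpart in h).

Coordinates and sequences on gene ``h`` and the exact block boundaries are a
synthetic reconstruction built so that every documented landmark of the
scenario holds: S(g) = {(4,12),(25,36),(41,46),(51,59)}, |g[c1]| = 21 with
CDS exons {(1,4),(5,16),(17,21)}, the assembled MSpA has 5 multiblocks, the
PSpA induced for (c3, g) has 3 blocks, g[c1] and h[c3] are splicing
orthologs, and projecting h[c4] onto g predicts the two-exon CDS
AAGCAGGTCTGGGGTGATTGA.
"""

from __future__ import annotations

from .model import Block, GeneModel, MSpA, Multiblock, PSpA, Segment
from .pspa import PSpASet

GENE_G = (
    "GTC" "ATGGC" "ATGC" "GTAAGTTTTCAG" "AAGCAGGTCTGG" "GTAG" "CCTGAA"
    "GTAG" "GGTGATTGA" "CCC"
)  # length 62
GENE_H = (
    "GTAC" "ATGC" "GTTTTCAG" "AAACAGGTCTGG" "GTAG" "CCTGAG" "GTCAG"
    "GGTGATTGA" "GTTTTCAG"
)  # length 60


def _seg(seq_id: str, start: int, end: int) -> Segment:
    return Segment(seq_id, start, end)


def gene_models() -> dict[str, GeneModel]:
    """The two gene models of the worked example."""
    g = GeneModel(
        "g",
        GENE_G,
        {
            "c1": (_seg("g", 9, 12), _seg("g", 25, 36), _seg("g", 51, 55)),
            "c2": (_seg("g", 4, 12), _seg("g", 25, 30), _seg("g", 41, 46), _seg("g", 51, 59)),
        },
    )
    h = GeneModel(
        "h",
        GENE_H,
        {
            "c3": (_seg("h", 5, 8), _seg("h", 17, 28), _seg("h", 44, 48)),
            "c4": (_seg("h", 17, 28), _seg("h", 44, 52)),
        },
    )
    return {"g": g, "h": h}


def pspa_set() -> PSpASet:
    """The four curated PSpAs W, X, Y, Z of the worked example."""
    out = PSpASet()
    out.add(PSpA("c3", "g", (
        Block(_seg("c3", 1, 4), _seg("g", 9, 12), 1.0),
        Block(_seg("c3", 5, 16), _seg("g", 25, 36), 11 / 12),
        Block(_seg("c3", 17, 21), _seg("g", 51, 55), 1.0),
    )))
    out.add(PSpA("c4", "g", (
        Block(_seg("c4", 1, 12), _seg("g", 25, 36), 11 / 12),
        Block(_seg("c4", 13, 21), _seg("g", 51, 59), 1.0),
    )))
    out.add(PSpA("c1", "h", (
        Block(_seg("c1", 1, 4), _seg("h", 1, 4), 0.5),  # spurious low-PID block
        Block(_seg("c1", 5, 16), _seg("h", 17, 28), 11 / 12),
        Block(_seg("c1", 17, 19), _seg("h", 44, 46), 1.0),
        Block(_seg("c1", 20, 21), _seg("h", 47, 48), 1.0),
    )))
    out.add(PSpA("c2", "h", (
        Block(_seg("c2", 1, 9)),  # deleted: no counterpart in h
        Block(_seg("c2", 10, 15), _seg("h", 17, 22), 5 / 6),
        Block(_seg("c2", 16, 21), _seg("h", 33, 38), 5 / 6),
        Block(_seg("c2", 22, 30), _seg("h", 44, 52), 1.0),
    )))
    return out


def reference_mspa() -> MSpA:
    """The five-multiblock MSpA of the worked example.

    Multiblocks 2, 3 and 5 carry c3 (so the induced PSpA of (c3, g) has three
    blocks); multiblock 1 holds only the spurious h segment isolated during
    conflict splitting; multiblock 4 covers the g region absent from every h
    CDS.
    """
    return MSpA(
        cds_ids=frozenset({"c1", "c2", "c3", "c4"}),
        gene_ids=frozenset({"g", "h"}),
        multiblocks=(
            Multiblock({"h": _seg("h", 1, 4)}),
            Multiblock({
                "g": _seg("g", 4, 12), "h": _seg("h", 5, 8),
                "c1": _seg("c1", 1, 4), "c2": _seg("c2", 1, 9), "c3": _seg("c3", 1, 4),
            }),
            Multiblock({
                "g": _seg("g", 25, 36), "h": _seg("h", 17, 28),
                "c1": _seg("c1", 5, 16), "c2": _seg("c2", 10, 15),
                "c3": _seg("c3", 5, 16), "c4": _seg("c4", 1, 12),
            }),
            Multiblock({
                "g": _seg("g", 41, 46), "h": _seg("h", 33, 38), "c2": _seg("c2", 16, 21),
            }),
            Multiblock({
                "g": _seg("g", 51, 59), "h": _seg("h", 44, 52),
                "c1": _seg("c1", 17, 21), "c2": _seg("c2", 22, 30),
                "c3": _seg("c3", 17, 21), "c4": _seg("c4", 13, 21),
            }),
        ),
    )


#: Sequence of the two-exon CDS predictable on gene g by homology with h[c4].
PREDICTED_G_CDS = "AAGCAGGTCTGGGGTGATTGA"
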