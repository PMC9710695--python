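"""A toy gene-family simulator with exact ground truth.

Generates a small family: an ancestral gene with an exon-intron structure and
a set of alternative transcripts (exon subsets) is created at the root of a
species tree and evolved along its branches by per-site substitutions, with
optional exon-skip and transcript-loss events and optional codon-length
intron deletions.  Every leaf yields a gene model; the simulator also emits

* the true MSA of all genes and CDSs (column-exact, since exons never gain
  or lose positions),
* the true splicing-ortholog groups (CDSs descending from the same ancestral
  transcript without any alternative-splicing event on their path), and
* the per-exon homology map.

The point of the simulator is exact, column-trivial truth for pipeline
testing, not realism: substitutions are i.i.d. across sites, exon boundaries
are immutable, and indels (when enabled) touch introns only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Phylo

from .derive import MultipleAlignment, OrthologyPartition
from .model import GeneModel, MspaError, Segment

DEFAULT_TREE = "((sp1:0.5,sp2:0.5):0.5,(sp3:0.5,sp4:0.5):0.25,sp5:0.75);"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated family.

    Exon lengths are multiples of 3 so the splicing-ortholog mod-3 rule is
    exact by construction; the substitution probability per site on a branch
    is ``substitution_rate * branch_length`` (capped at 0.75).
    """

    tree: str = DEFAULT_TREE
    exon_count: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (30, 90)
    intron_length: tuple[int, int] = (20, 60)
    substitution_rate: float = 0.05
    transcript_count: tuple[int, int] = (1, 3)
    exon_skip_prob: float = 0.1
    transcript_loss_prob: float = 0.05
    intron_deletion_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exon_count", "exon_length", "intron_length", "transcript_count"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise MspaError(f"empty or invalid range for {name}: ({lo}, {hi})")
        if self.substitution_rate < 0:
            raise MspaError("substitution rate must be >= 0")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth emitted alongside a simulated family."""

    msa: MultipleAlignment
    ortholog_groups: OrthologyPartition
    exon_homology: dict[str, dict[Segment, int]]  # gene/CDS exon -> root exon index


@dataclass
class _Lineage:
    """One gene lineage during the tree walk (root columns + transcript set)."""

    columns: list[int]  # root-column index of each retained position
    chars: list[str]
    exon_cols: list[tuple[int, int]]  # root-column span of each root exon
    transcripts: dict[str, tuple[tuple[int, ...], int]]  # name -> (exon idxs, lineage id)


def _mutate(rng: np.random.Generator, lineage: _Lineage, p_sub: float) -> None:
    n = len(lineage.chars)
    hits = np.nonzero(rng.random(n) < p_sub)[0]
    for i in hits:
        current = lineage.chars[i]
        choices = [b for b in "ACGT" if b != current]
        lineage.chars[i] = choices[rng.integers(0, 3)]


def _delete_introns(rng: np.random.Generator, lineage: _Lineage, prob: float,
                    rng_len: tuple[int, int]) -> None:
    """Codon-length deletions confined to intronic root columns."""
    exonic = set()
    for lo, hi in lineage.exon_cols:
        exonic.update(range(lo, hi + 1))
    if rng.random() >= prob:
        return
    intronic = [k for k, col in enumerate(lineage.columns) if col not in exonic]
    if len(intronic) < 6:
        return
    span = 3 * int(rng.integers(1, max(2, min(rng_len) // 3)))
    start = int(rng.integers(0, max(1, len(intronic) - span)))
    doomed = set(intronic[start : start + span])
    # only delete a contiguous run of intronic positions
    doomed = {k for k in doomed if lineage.columns[k] not in exonic}
    lineage.columns = [c for k, c in enumerate(lineage.columns) if k not in doomed]
    lineage.chars = [c for k, c in enumerate(lineage.chars) if k not in doomed]


def simulate_family(config: SimConfig) -> tuple[dict[str, GeneModel], FamilyTruth]:
    """Simulate one gene family; identical config (incl. seed) gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    tree = Phylo.read(io.StringIO(config.tree), "newick")
    leaves = tree.get_terminals()
    if any(leaf.name is None for leaf in leaves):
        raise MspaError("all tree leaves must be named")

    # --- root gene -------------------------------------------------------
    n_exons = int(rng.integers(config.exon_count[0], config.exon_count[1] + 1))
    exon_lens = [
        3 * int(rng.integers(config.exon_length[0] // 3, config.exon_length[1] // 3 + 1))
        for _ in range(n_exons)
    ]
    intron_lens = [
        int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        for _ in range(n_exons + 1)
    ]
    chars: list[str] = []
    exon_cols: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_exons):
        chars.extend(_BASES[rng.integers(0, 4, intron_lens[i])])
        pos += intron_lens[i]
        exon_cols.append((pos, pos + exon_lens[i] - 1))
        chars.extend(_BASES[rng.integers(0, 4, exon_lens[i])])
        pos += exon_lens[i]
    chars.extend(_BASES[rng.integers(0, 4, intron_lens[-1])])
    root_len = len(chars)

    # root transcripts: distinct exon subsets; the first keeps every exon
    n_tr = int(rng.integers(config.transcript_count[0], config.transcript_count[1] + 1))
    subsets: list[tuple[int, ...]] = [tuple(range(n_exons))]
    attempts = 0
    while len(subsets) < n_tr and attempts < 200:
        attempts += 1
        # fixed per-exon keep probability for root isoform diversity, so root
        # transcripts differ even when branch-level skipping is switched off
        keep = tuple(i for i in range(n_exons) if rng.random() > 0.3)
        if len(keep) >= 1 and keep not in subsets:
            subsets.append(keep)
    transcripts = {f"t{j + 1}": (subset, j) for j, subset in enumerate(subsets)}
    next_lineage = len(subsets)

    root = _Lineage(list(range(root_len)), list(chars), exon_cols, transcripts)

    # --- evolve along the tree ------------------------------------------
    models: dict[str, GeneModel] = {}
    truth_rows: dict[str, str] = {}
    lineage_of: dict[str, int] = {}  # CDS id -> ancestral-transcript lineage
    exon_homology: dict[str, dict[Segment, int]] = {}

    def walk(clade, lineage: _Lineage) -> None:
        nonlocal next_lineage
        for child in clade.clades:
            branch = child.branch_length or 0.0
            sub = _Lineage(
                list(lineage.columns),
                list(lineage.chars),
                lineage.exon_cols,
                {k: v for k, v in lineage.transcripts.items()},
            )
            p_sub = min(0.75, config.substitution_rate * branch)
            if p_sub > 0:
                _mutate(rng, sub, p_sub)
            if config.intron_deletion_prob > 0:
                _delete_introns(rng, sub, config.intron_deletion_prob, config.intron_length)
            # transcript-level events
            new_transcripts: dict[str, tuple[tuple[int, ...], int]] = {}
            for name in sorted(sub.transcripts):
                subset, lin = sub.transcripts[name]
                if len(new_transcripts) and rng.random() < config.transcript_loss_prob:
                    continue  # lost (never lose the last transcript)
                if len(subset) > 1 and rng.random() < config.exon_skip_prob:
                    drop = int(rng.integers(0, len(subset)))
                    new_subset = tuple(e for k, e in enumerate(subset) if k != drop)
                    if new_subset not in {s for s, _ in new_transcripts.values()}:
                        subset = new_subset
                        lin = next_lineage  # a splicing event starts a new lineage
                        next_lineage += 1
                new_transcripts[name] = (subset, lin)
            sub.transcripts = new_transcripts
            if child.is_terminal():
                _emit(child.name, sub)
            else:
                walk(child, sub)

    def _emit(name: str, lineage: _Lineage) -> None:
        gene_id = name
        seq = "".join(lineage.chars)
        col_to_pos = {col: k + 1 for k, col in enumerate(lineage.columns)}
        gene_exons: list[Segment] = []
        for lo, hi in lineage.exon_cols:
            gene_exons.append(Segment(gene_id, col_to_pos[lo], col_to_pos[hi]))
        cds_models: dict[str, tuple[Segment, ...]] = {}
        homology: dict[Segment, int] = {e: i for i, e in enumerate(gene_exons)}
        for tname in sorted(lineage.transcripts):
            subset, lin = lineage.transcripts[tname]
            cds_id = f"{gene_id}.{tname}"
            cds_models[cds_id] = tuple(gene_exons[i] for i in subset)
            lineage_of[cds_id] = lin
        models[gene_id] = GeneModel(gene_id, seq, cds_models)
        exon_homology[gene_id] = homology
        # truth-MSA rows over root columns
        row = ["-"] * root_len
        for k, col in enumerate(lineage.columns):
            row[col] = lineage.chars[k]
        truth_rows[gene_id] = "".join(row)
        for tname in sorted(lineage.transcripts):
            subset, _ = lineage.transcripts[tname]
            cds_id = f"{gene_id}.{tname}"
            crow = ["-"] * root_len
            for i in subset:
                lo, hi = lineage.exon_cols[i]
                for col in range(lo, hi + 1):
                    k = col_to_pos[col] - 1
                    crow[col] = lineage.chars[k]
            truth_rows[cds_id] = "".join(crow)

    walk(tree.root, root)

    groups: dict[int, set[str]] = {}
    for cds_id, lin in lineage_of.items():
        groups.setdefault(lin, set()).add(cds_id)
    truth = FamilyTruth(
        msa=MultipleAlignment(truth_rows, root_len),
        ortholog_groups=OrthologyPartition(frozenset(frozenset(g) for g in groups.values())),
        exon_homology=exon_homology,
    )
    return models, truth
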