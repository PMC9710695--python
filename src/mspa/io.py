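"""File formats: FASTA, GFF3 gene models, a JSON gene-model dialect, MSpA
JSON, gapped-alignment output and small TSV reports.

GFF3 coordinates are 1-based inclusive, matching the package's internal
convention, so no shifting occurs.  CDS features are grouped by their
``Parent`` attribute (fallback ``transcript_id``, then ``ID``); reverse-strand
annotations are normalised by the reader to the coding strand
(reverse-complementing the gene sequence and flipping coordinates), since the
whole framework assumes coding-strand input.
"""

from __future__ import annotations

import csv
import json
from typing import Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .derive import MultipleAlignment, OrthologyPartition, PredictedCDS
from .model import GeneModel, MSpA, MspaError, Multiblock, Segment


# --- FASTA -----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 gene models ------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for field in text.strip().split(";"):
        if not field:
            continue
        key, _, value = field.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_models(gff_path, sequences: Mapping[str, str]) -> dict[str, GeneModel]:
    """Read gene models from GFF3 CDS features grouped by transcript.

    The GFF seqid column names the gene whose sequence must be present in
    ``sequences``.  Reverse-strand transcripts are normalised to the coding
    strand.
    """
    chains: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    with open(gff_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise MspaError(f"{gff_path}:{lineno}: expected 9 GFF columns")
            seqid, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "CDS":
                continue
            attributes = _parse_attributes(attrs)
            cds_id = attributes.get("Parent") or attributes.get("transcript_id") or attributes.get("ID")
            if cds_id is None:
                raise MspaError(f"{gff_path}:{lineno}: CDS feature without Parent/transcript_id/ID")
            if seqid not in sequences:
                raise MspaError(f"{gff_path}:{lineno}: no sequence for gene {seqid!r}")
            chains.setdefault((seqid, cds_id), []).append((int(start), int(end), strand))

    by_gene: dict[str, dict[str, tuple[Segment, ...]]] = {}
    normalised: dict[str, str] = dict(sequences)
    flipped: set[str] = set()
    for (gene_id, cds_id), exons in chains.items():
        strands = {s for _, _, s in exons}
        if len(strands) > 1:
            raise MspaError(f"CDS {cds_id}: mixed strands")
        strand = strands.pop()
        n = len(sequences[gene_id])
        if strand == "-":
            # normalise to the coding strand
            if gene_id not in flipped:
                if any(s == "+" for (g, _), ex in chains.items() if g == gene_id for _, _, s in ex):
                    raise MspaError(f"gene {gene_id}: mixed strand transcripts cannot be normalised")
                normalised[gene_id] = str(Seq(sequences[gene_id]).reverse_complement())
                flipped.add(gene_id)
            exons = [(n - e + 1, n - s + 1, "+") for s, e, _ in exons]
        segs = tuple(sorted(Segment(gene_id, s, e) for s, e, _ in exons))
        by_gene.setdefault(gene_id, {})[cds_id] = segs

    return {
        gene_id: GeneModel(gene_id, normalised[gene_id], cds_models)
        for gene_id, cds_models in sorted(by_gene.items())
    }


def write_gene_models(models: Mapping[str, GeneModel], path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for gene_id in sorted(models):
            model = models[gene_id]
            handle.write(
                f"{gene_id}\tmspa\tgene\t1\t{model.length}\t.\t+\t.\tID={gene_id}\n"
            )
            for cds_id in model.cds_ids():
                for exon in model.cds_models[cds_id]:
                    handle.write(
                        f"{gene_id}\tmspa\tCDS\t{exon.start}\t{exon.end}\t.\t+\t0\t"
                        f"ID=cds:{cds_id};Parent={cds_id}\n"
                    )


# --- JSON gene-model dialect ----------------------------------------------

def read_gene_models_json(path, sequences: Mapping[str, str]) -> dict[str, GeneModel]:
    """Read {gene_id, cds: {cds_id: [[a, b], ...]}} records (list or single)."""
    with open(path) as handle:
        data = json.load(handle)
    if isinstance(data, dict):
        data = [data]
    models = {}
    for record in data:
        gene_id = record["gene_id"]
        if gene_id not in sequences:
            raise MspaError(f"no sequence for gene {gene_id!r}")
        cds_models = {
            cds_id: tuple(Segment(gene_id, a, b) for a, b in chain)
            for cds_id, chain in record["cds"].items()
        }
        models[gene_id] = GeneModel(gene_id, sequences[gene_id], cds_models)
    return models


# --- MSpA JSON -------------------------------------------------------------

def write_mspa_json(mspa: MSpA, path) -> None:
    data = {
        "cds_ids": sorted(mspa.cds_ids),
        "gene_ids": sorted(mspa.gene_ids),
        "multiblocks": [
            {sid: [seg.start, seg.end] for sid, seg in mb.entries.items()}
            for mb in mspa.multiblocks
        ],
    }
    with open(path, "w") as handle:
        json.dump(data, handle, indent=1)
        handle.write("\n")


def read_mspa_json(path) -> MSpA:
    with open(path) as handle:
        data = json.load(handle)
    multiblocks = tuple(
        Multiblock({sid: Segment(sid, a, b) for sid, (a, b) in mb.items()})
        for mb in data["multiblocks"]
    )
    return MSpA(frozenset(data["cds_ids"]), frozenset(data["gene_ids"]), multiblocks)


# --- alignments and reports ------------------------------------------------

def write_alignment_fasta(msa: MultipleAlignment, path) -> None:
    write_fasta(dict(msa.rows), path)


def write_alignment_clustal(msa: MultipleAlignment, path) -> None:
    from Bio.Align import MultipleSeqAlignment
    from Bio import AlignIO

    records = [SeqRecord(Seq(row), id=name, description="") for name, row in msa.rows.items()]
    AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")


def read_alignment_fasta(path) -> MultipleAlignment:
    rows = read_fasta(path)
    width = len(next(iter(rows.values()))) if rows else 0
    return MultipleAlignment(rows, width)


def write_orthology_tsv(partition: OrthologyPartition, path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["group_id", "cds_id"])
        for i, group in enumerate(sorted(partition.groups, key=lambda g: sorted(g)), start=1):
            for cds_id in sorted(group):
                writer.writerow([i, cds_id])


def read_orthology_tsv(path) -> OrthologyPartition:
    groups: dict[str, set[str]] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["group_id", "cds_id"]:
            raise MspaError(f"malformed orthology TSV header in {path}")
        for row in reader:
            if row:
                groups.setdefault(row[0], set()).add(row[1])
    return OrthologyPartition(frozenset(frozenset(g) for g in groups.values()))


def write_predictions(predictions: list[PredictedCDS], gff_path, fasta_path) -> None:
    sequences = {}
    with open(gff_path, "w") as handle:
        handle.write("##gff-version 3\n")
        for i, pred in enumerate(predictions, start=1):
            pred_id = f"{pred.gene_id}.pred{i}"
            sequences[pred_id] = pred.sequence
            for exon in pred.exons:
                handle.write(
                    f"{pred.gene_id}\tmspa\tCDS\t{exon.start}\t{exon.end}\t.\t+\t0\t"
                    f"ID=cds:{pred_id};Parent={pred_id};source_cds={pred.source_cds_id}\n"
                )
    write_fasta(sequences, fasta_path)
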