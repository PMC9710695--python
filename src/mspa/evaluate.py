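"""Evaluation metrics for CDS alignments, ortholog partitions and predictions.

MSA accuracy follows the aligned-nucleotide-pair convention: *precision* is
the fraction of aligned pairs of the estimated alignment also present in the
true alignment, *recall* the converse, and the F-score their harmonic mean.
Partition agreement uses the Rand index.  Prediction accuracy supports the
strict criterion (100% sequence identity) and the relaxed one (>90% global
percent identity plus reciprocal best hits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from sklearn.metrics import rand_score

from .derive import MultipleAlignment, OrthologyPartition
from .model import MspaError
from .pspa import DEFAULT_SCORING, global_pid

Pair = tuple[tuple[str, int], tuple[str, int]]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f_score: float


def _f_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def aligned_pairs(msa: MultipleAlignment) -> set[Pair]:
    """Aligned nucleotide pairs: ((id1, pos1), (id2, pos2)) with id1 < id2,
    extracted from columns where both rows are non-gap.  Positions are
    1-based positions in the ungapped sequences."""
    ids = sorted(msa.rows)
    pos = {sid: 0 for sid in ids}
    pairs: set[Pair] = set()
    for col in range(msa.n_columns):
        present = []
        for sid in ids:
            if msa.rows[sid][col] != "-":
                pos[sid] += 1
                present.append((sid, pos[sid]))
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                pairs.add((present[i], present[j]))
    return pairs


def msa_scores(estimated: MultipleAlignment, truth: MultipleAlignment) -> PRF:
    """Precision / recall / F-score of an estimated MSA against the truth."""
    if set(estimated.rows) != set(truth.rows):
        raise MspaError("estimated and true alignments cover different sequence sets")
    for sid in estimated.rows:
        if estimated.ungapped(sid) != truth.ungapped(sid):
            raise MspaError(f"row {sid} ungaps to different sequences in the two alignments")
    est = aligned_pairs(estimated)
    tru = aligned_pairs(truth)
    shared = len(est & tru)
    precision = shared / len(est) if est else 1.0
    recall = shared / len(tru) if tru else 1.0
    return PRF(precision, recall, _f_score(precision, recall))


def rand_index(estimated: OrthologyPartition, truth: OrthologyPartition) -> float:
    """Fraction of element pairs on which two partitions agree."""
    elements_e = {sid for g in estimated.groups for sid in g}
    elements_t = {sid for g in truth.groups for sid in g}
    if elements_e != elements_t:
        raise MspaError("partitions cover different element sets")
    order = sorted(elements_e)
    if len(order) < 2:
        return 1.0
    return float(rand_score(truth.as_labels(order), estimated.as_labels(order)))


def _best_hits(queries: dict[str, str], targets: dict[str, str],
               scoring) -> dict[str, tuple[str, float]]:
    """Best-PID target for each query; ties broken by lexicographic id."""
    out = {}
    for qid in sorted(queries):
        best_id, best_pid = None, -1.0
        for tid in sorted(targets):
            pid = global_pid(queries[qid], targets[tid], scoring)
            if pid > best_pid:
                best_id, best_pid = tid, pid
        if best_id is not None:
            out[qid] = (best_id, best_pid)
    return out


def prediction_scores(
    predicted: dict[str, str] | Sequence[str],
    truth: dict[str, str] | Sequence[str],
    mode: str = "strict100",
    *,
    min_pid: float = 0.9,
    scoring=DEFAULT_SCORING,
) -> PRF:
    """Precision / recall / F-score of a predicted CDS set against a true set.

    ``strict100`` matches CDSs by exact sequence identity; ``rbh90`` matches
    reciprocal best hits with global-alignment PID above ``min_pid``.
    Inputs may be id->sequence mappings or plain sequence collections.
    """
    if not isinstance(predicted, dict):
        predicted = {f"P{i + 1}": s for i, s in enumerate(predicted)}
    if not isinstance(truth, dict):
        truth = {f"T{i + 1}": s for i, s in enumerate(truth)}
    if not predicted or not truth:
        matched_p = matched_t = 0
    elif mode == "strict100":
        true_seqs = set(truth.values())
        pred_seqs = set(predicted.values())
        matched_p = sum(1 for s in predicted.values() if s in true_seqs)
        matched_t = sum(1 for s in truth.values() if s in pred_seqs)
    elif mode == "rbh90":
        fwd = _best_hits(predicted, truth, scoring)
        rev = _best_hits(truth, predicted, scoring)
        pairs = {
            (pid_, tid)
            for pid_, (tid, score) in fwd.items()
            if score > min_pid and rev.get(tid, (None,))[0] == pid_
        }
        matched_p = len({p for p, _ in pairs})
        matched_t = len({t for _, t in pairs})
    else:
        raise MspaError(f"unknown mode {mode!r} (expected 'strict100' or 'rbh90')")
    precision = matched_p / len(predicted) if predicted else 1.0
    recall = matched_t / len(truth) if truth else 1.0
    return PRF(precision, recall, _f_score(precision, recall))
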