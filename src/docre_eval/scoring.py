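"""Equivalence-aware matching of predicted triplets against the DocRE reference.

A predicted 〈source, type, target〉 matches a reference relation when the
relation type is identical (exact label comparison) and each normalized
argument form belongs to the corresponding acceptable-form set.  True
positives are counted on the reference side: a reference relation matched by
several predictions yields one TP and the surplus predictions are ignored
(neither TP nor FP); predictions matching no reference are false positives;
unmatched reference relations are false negatives.  Per-run F1 scores are
averaged over well-formed runs to give the per-document accuracy, and
macro-averaged over documents per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from docre_eval.corpus import normalize_form
from docre_eval.reference import DocREReference
from docre_eval.repair import ParsedRun

__all__ = ["MatchResult", "DocumentAccuracy", "match_relations", "document_accuracy", "macro_average_accuracy"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchResult:
    """Per-run match counts and scores against one document's reference."""

    key: tuple[str, str, int]
    TP: int
    FP: int
    FN: int
    n_matched_predictions: int
    precision: float
    recall: float
    f1: float


@dataclass(frozen=True)
class DocumentAccuracy:
    """Mean F1 over the well-formed runs of one (model, document) pair."""

    model: str
    doc_id: str
    mean_f1: float
    n_wellformed_runs: int


def match_relations(run: ParsedRun, ref: DocREReference, case_insensitive_types: bool = False) -> MatchResult:
    """Score one well-formed run against the document reference.

    ``TP + FN`` always equals the number of reference relations.  A single
    prediction may support the TP of several distinct reference relations
    (TP is reference-side); this is logged when it occurs.  With both the
    prediction list and the reference empty, precision = recall = F1 = 1
    (a vacuously perfect extraction).

    ``case_insensitive_types`` relaxes the relation-type comparison; off by
    default because type confusions are genuine errors under a strict schema.
    """
    if run.status == "unrecoverable":
        raise ValueError(f"match_relations: run {run.key} is unrecoverable; caller must filter")

    def type_key(label: str) -> str:
        return label.casefold() if case_insensitive_types else label

    preds = [
        (type_key(p.type), normalize_form(p.source), normalize_form(p.target))
        for p in run.relations
    ]
    matched_refs = 0
    unmatched_refs = 0
    pred_matches = [False] * len(preds)
    for rel in ref.relations:
        hit = False
        for i, (ptype, psrc, ptgt) in enumerate(preds):
            if ptype == type_key(rel.type) and psrc in rel.source.forms and ptgt in rel.target.forms:
                hit = True
                pred_matches[i] = True
        if hit:
            matched_refs += 1
        else:
            unmatched_refs += 1
    n_matched_predictions = sum(pred_matches)
    if n_matched_predictions > matched_refs:
        logger.debug(
            "run %s: %d predictions matched %d references (duplicates ignored)",
            run.key, n_matched_predictions, matched_refs,
        )
    TP = matched_refs
    FP = len(preds) - n_matched_predictions
    FN = unmatched_refs
    if not preds and not ref.relations:
        precision = recall = f1 = 1.0
    else:
        precision = TP / (TP + FP) if TP + FP else 0.0
        recall = TP / (TP + FN) if TP + FN else 1.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MatchResult(
        key=run.key, TP=TP, FP=FP, FN=FN,
        n_matched_predictions=n_matched_predictions,
        precision=precision, recall=recall, f1=f1,
    )


def document_accuracy(results: Sequence[MatchResult]) -> DocumentAccuracy:
    """Mean F1 of the well-formed runs of one (model, document) pair."""
    if not results:
        raise ValueError("document_accuracy: no well-formed runs for this document")
    models = {r.key[0] for r in results}
    docs = {r.key[1] for r in results}
    if len(models) != 1 or len(docs) != 1:
        raise ValueError(f"document_accuracy: results span several (model, doc) pairs: {models} x {docs}")
    return DocumentAccuracy(
        model=next(iter(models)),
        doc_id=next(iter(docs)),
        mean_f1=sum(r.f1 for r in results) / len(results),
        n_wellformed_runs=len(results),
    )


def macro_average_accuracy(docs: Iterable[DocumentAccuracy]) -> float:
    """Unweighted mean of per-document mean F1 (the model's macro accuracy)."""
    docs = list(docs)
    if not docs:
        raise ValueError("macro_average_accuracy: empty document collection")
    return sum(d.mean_f1 for d in docs) / len(docs)
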