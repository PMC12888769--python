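"""End-to-end orchestration: corpus + run ensemble in, evaluation report out.

The pipeline sequences reference building (equivalence and/or strict mode),
output parsing and repair, per-run matching, per-document accuracy, Fleiss
kappa consistency, document covariates and the correlation analysis, and
assembles one report.  Every excluded run or document is recorded once with
a machine-readable reason code; all tabular outputs are sorted by
(model, doc_id) so reruns are byte-stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from docre_eval._version import __version__ as _pkg_version
from docre_eval.consistency import KappaResult, build_rating_matrix, fleiss_kappa, macro_average_consistency
from docre_eval.corpus import AnnotatedDocument, read_corpus
from docre_eval.reference import DocREReference, build_docre_reference
from docre_eval.repair import ParsedRun, RawRunOutput, parse_run, read_raw_runs, tabulate_validity
from docre_eval.scoring import DocumentAccuracy, MatchResult, document_accuracy, macro_average_accuracy, match_relations
from docre_eval.stats import DocumentRecord, correlation_report, document_metrics, records_frame

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "evaluate_ensemble"]

logger = logging.getLogger(__name__)

MODES = ("equivalence", "strict")


@dataclass(frozen=True)
class PipelineConfig:
    """File-level configuration of one pipeline invocation."""

    corpus_path: str
    predictions_path: str
    corpus_dialect: str = "canonical-json"
    models: Optional[tuple[str, ...]] = None  # None = every model present
    modes: tuple[str, ...] = MODES
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("at least one accuracy mode must be selected")
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}")


@dataclass
class RunReport:
    """Everything one evaluation computes, recomputable from inputs + config."""

    #: per (model, mode): macro accuracy; per model: macro consistency
    macro: pd.DataFrame
    #: per-model validity proportions (recoverable / unrecoverable / valid)
    validity: pd.DataFrame
    #: per-run match scores, per mode
    run_scores: dict[str, pd.DataFrame]
    #: one DocumentRecord per (model, doc), per mode
    records: dict[str, list[DocumentRecord]]
    #: per-mode correlation analyses (accuracy vs consistency + covariate matrix)
    correlations: dict[str, dict]
    #: (model, doc_id, reason_code) exclusions, each exactly once
    exclusions: list[tuple[str, str, str]]
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        corr = {}
        for mode, rep in self.correlations.items():
            corr[mode] = {}
            for model, entry in rep.items():
                e = dict(entry)
                mat = e.pop("spearman_matrix")
                e["spearman_matrix"] = {c: {r: (None if pd.isna(v) else float(v)) for r, v in mat[c].items()}
                                        for c in mat.columns}
                corr[mode][model] = e
        return {
            "macro": self.macro.to_dict(orient="records"),
            "validity": self.validity.to_dict(orient="records"),
            "correlations": corr,
            "exclusions": [list(x) for x in self.exclusions],
            "provenance": self.provenance,
        }


def evaluate_ensemble(
    documents: Sequence[AnnotatedDocument],
    raw_runs: Sequence[RawRunOutput],
    modes: Sequence[str] = MODES,
    models: Optional[Sequence[str]] = None,
    min_docs_for_correlation: int = 3,
) -> RunReport:
    """Evaluate a parsed-in-memory ensemble against an annotated corpus.

    This is the library entry point the file-based :func:`run_pipeline`
    wraps.  Documents without at least one well-formed run are excluded from
    accuracy; documents without at least two are excluded from consistency;
    the correlation analysis uses documents carrying both scores.
    """
    docs_by_id = {d.doc_id: d for d in documents}
    refs: dict[str, dict[str, DocREReference]] = {
        mode: {d.doc_id: build_docre_reference(d, use_equivalence=(mode == "equivalence")) for d in documents}
        for mode in modes
    }
    metrics = {d.doc_id: document_metrics(d) for d in documents}

    parsed = [parse_run(r) for r in sorted(raw_runs, key=lambda r: (r.model, r.doc_id, r.run_index))]
    if models is not None:
        parsed = [p for p in parsed if p.model in set(models)]
    if not parsed:
        raise ValueError("evaluate_ensemble: no runs to evaluate")
    validity = tabulate_validity(parsed)

    by_model_doc: dict[tuple[str, str], list[ParsedRun]] = {}
    for p in parsed:
        if p.doc_id not in docs_by_id:
            raise ValueError(f"run {p.key} references unknown document {p.doc_id!r}")
        by_model_doc.setdefault((p.model, p.doc_id), []).append(p)

    all_models = sorted({m for m, _ in by_model_doc})
    exclusions: list[tuple[str, str, str]] = []
    for model in all_models:
        covered = {doc for m, doc in by_model_doc if m == model}
        for doc_id in sorted(docs_by_id):
            if doc_id not in covered:
                exclusions.append((model, doc_id, "missing_runs"))
                logger.warning("model %s: no runs for document %s; skipped", model, doc_id)

    run_scores: dict[str, list[MatchResult]] = {mode: [] for mode in modes}
    doc_accuracy: dict[str, dict[tuple[str, str], DocumentAccuracy]] = {mode: {} for mode in modes}
    doc_kappa: dict[tuple[str, str], KappaResult] = {}
    for (model, doc_id), runs in sorted(by_model_doc.items()):
        wellformed = [r for r in runs if r.status != "unrecoverable"]
        if not wellformed:
            exclusions.append((model, doc_id, "no_wellformed_runs"))
            continue
        for mode in modes:
            ref = refs[mode][doc_id]
            results = [match_relations(r, ref) for r in wellformed]
            run_scores[mode].extend(results)
            doc_accuracy[mode][(model, doc_id)] = document_accuracy(results)
        if len(wellformed) >= 2:
            doc_kappa[(model, doc_id)] = fleiss_kappa(build_rating_matrix(wellformed))
        else:
            exclusions.append((model, doc_id, "insufficient_runs_for_consistency"))

    macro_rows = []
    for model in all_models:
        row: dict = {"model": model}
        kappas = [k for (m, _), k in doc_kappa.items() if m == model]
        row["macro_consistency"] = macro_average_consistency(kappas) if kappas else float("nan")
        row["n_documents_consistency"] = len(kappas)
        for mode in modes:
            accs = [a for (m, _), a in doc_accuracy[mode].items() if m == model]
            row[f"macro_accuracy_{mode}"] = macro_average_accuracy(accs) if accs else float("nan")
            row["n_documents_accuracy"] = len(accs)
        macro_rows.append(row)
    macro = pd.DataFrame(macro_rows)

    records: dict[str, list[DocumentRecord]] = {}
    correlations: dict[str, dict] = {}
    for mode in modes:
        recs = []
        for (model, doc_id), acc in sorted(doc_accuracy[mode].items()):
            kap = doc_kappa.get((model, doc_id))
            if kap is None:
                continue
            length, n_ent, n_rel, _ = metrics[doc_id]
            recs.append(DocumentRecord(
                model=model, doc_id=doc_id,
                accuracy=acc.mean_f1, consistency=kap.kappa,
                length_bytes=length, n_entities=n_ent, n_relations=n_rel,
            ))
        records[mode] = recs
        eligible = [r for r in recs]
        per_model_counts = pd.Series([r.model for r in eligible]).value_counts() if eligible else pd.Series(dtype=int)
        usable = [r for r in eligible if per_model_counts.get(r.model, 0) >= min_docs_for_correlation]
        dropped_models = set(per_model_counts[per_model_counts < min_docs_for_correlation].index)
        for m in sorted(dropped_models):
            exclusions.append((m, "*", f"too_few_documents_for_correlation_{mode}"))
        correlations[mode] = correlation_report(usable) if usable else {}

    score_columns = ["model", "doc_id", "run", "TP", "FP", "FN", "precision", "recall", "f1"]
    score_frames = {
        mode: pd.DataFrame.from_records([
            {"model": r.key[0], "doc_id": r.key[1], "run": r.key[2],
             "TP": r.TP, "FP": r.FP, "FN": r.FN,
             "precision": r.precision, "recall": r.recall, "f1": r.f1}
            for r in run_scores[mode]
        ], columns=score_columns).sort_values(["model", "doc_id", "run"]).reset_index(drop=True)
        for mode in modes
    }

    seen: set[tuple[str, str, str]] = set()
    unique_exclusions = []
    for ex in exclusions:
        if ex not in seen:
            seen.add(ex)
            unique_exclusions.append(ex)

    return RunReport(
        macro=macro,
        validity=validity,
        run_scores=score_frames,
        records=records,
        correlations=correlations,
        exclusions=unique_exclusions,
        provenance={"version": _pkg_version, "modes": list(modes),
                    "n_documents": len(documents), "n_runs": len(parsed)},
    )


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """File-based pipeline: read corpus and predictions, evaluate, optionally write outputs."""
    documents = read_corpus(cfg.corpus_path, dialect=cfg.corpus_dialect)
    raw_runs = read_raw_runs(cfg.predictions_path)
    report = evaluate_ensemble(documents, raw_runs, modes=cfg.modes, models=cfg.models)
    report.provenance.update({"config": {
        "corpus_path": str(cfg.corpus_path), "predictions_path": str(cfg.predictions_path),
        "corpus_dialect": cfg.corpus_dialect, "models": list(cfg.models) if cfg.models else None,
        "modes": list(cfg.modes), "seed": cfg.seed,
    }})
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write the report as JSON plus diff-stable TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_json(), indent=1, ensure_ascii=False) + "\n", encoding="utf-8")
    report.macro.to_csv(out / "macro.tsv", sep="\t", index=False)
    report.validity.to_csv(out / "validity.tsv", sep="\t", index=False)
    for mode, frame in report.run_scores.items():
        frame.to_csv(out / f"run_scores_{mode}.tsv", sep="\t", index=False)
    for mode, recs in report.records.items():
        if recs:
            records_frame(recs).to_csv(out / f"document_records_{mode}.tsv", sep="\t", index=False)
    with (out / "exclusions.tsv").open("w", encoding="utf-8") as fh:
        fh.write("model\tdoc_id\treason\n")
        for model, doc_id, reason in report.exclusions:
            fh.write(f"{model}\t{doc_id}\t{reason}\n")
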