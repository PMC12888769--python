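"""Document covariates, normality checks and the accuracy–consistency correlation analysis.

Each (model, document) pair contributes one observation: the document's mean
F1 (accuracy), its Fleiss kappa (consistency), its length in UTF-8 bytes and
its annotation complexity (number of entity mentions plus number of
text-bound relations, repetitions included).  Accuracy–consistency
association is assessed with Pearson, Spearman and Kendall tau-b tests at
the document level, after a Kolmogorov–Smirnov normality check of both score
distributions.

The K–S test is run against a normal with sample-estimated mean and standard
deviation.  With estimated parameters the test is anti-conservative (the
Lilliefors situation); results are annotated accordingly but not corrected,
since the check only gates whether the parametric coefficient is reported
alongside the rank-based ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from docre_eval.corpus import AnnotatedDocument

__all__ = [
    "DocumentRecord",
    "CorrelationResult",
    "document_metrics",
    "ks_normality",
    "correlate",
    "correlation_report",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ("accuracy", "consistency", "length_bytes", "complexity", "n_entities", "n_relations")


@dataclass(frozen=True)
class DocumentRecord:
    """One observation of the document-level correlation analysis."""

    model: str
    doc_id: str
    accuracy: float
    consistency: float
    length_bytes: int
    n_entities: int
    n_relations: int

    @property
    def complexity(self) -> int:
        return self.n_entities + self.n_relations


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int


def document_metrics(doc: AnnotatedDocument) -> tuple[int, int, int, int]:
    """(UTF-8 byte length, mention count, relation count, complexity) of a document.

    Counts include repeated mentions of the same entity; complexity is their
    sum with the relation count.
    """
    length = len(doc.text.encode("utf-8"))
    n_entities = len(doc.mentions)
    n_relations = len(doc.relations)
    return length, n_entities, n_relations, n_entities + n_relations


def ks_normality(values: Sequence[float], alpha: float = 0.05) -> tuple[float, float, bool]:
    """One-sample K–S test against a normal with sample-estimated mean and sd.

    Returns ``(statistic, p_value, passes)`` with ``passes`` true when the
    normality hypothesis is not rejected at ``alpha``.  Anti-conservative
    because the parameters are estimated from the same sample.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValueError(f"ks_normality: need >= 8 values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("ks_normality: degenerate (zero-variance) input")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return float(stat), float(p), bool(p >= alpha)


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> CorrelationResult:
    """Correlation coefficient and two-sided p-value for one of the three tests.

    ``method`` is ``pearson``, ``spearman`` (midrank ties) or ``kendall``
    (tau-b, tie-corrected).  Zero variance in either variable is an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("correlate: x and y must be equal-length 1-D sequences")
    if xa.size < 3:
        raise ValueError(f"correlate: need >= 3 observations, got {xa.size}")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("correlate: non-finite values present")
    for name, arr in (("x", xa), ("y", ya)):
        if np.ptp(arr) == 0:
            raise ValueError(f"correlate: {name} has zero variance; coefficient undefined")
    if method == "pearson":
        r = sps.pearsonr(xa, ya)
        coef, p = r.statistic, r.pvalue
    elif method == "spearman":
        coef, p = sps.spearmanr(xa, ya)
    elif method == "kendall":
        coef, p = sps.kendalltau(xa, ya, variant="b")
    else:
        raise ValueError(f"correlate: unknown method {method!r}")
    return CorrelationResult(method=method, coefficient=float(coef), p_value=float(p), n=int(xa.size))


def records_frame(records: Iterable[DocumentRecord]) -> pd.DataFrame:
    """DocumentRecords as a tidy DataFrame sorted by (model, doc_id)."""
    rows = [
        {
            "model": r.model, "doc_id": r.doc_id,
            "accuracy": r.accuracy, "consistency": r.consistency,
            "length_bytes": r.length_bytes, "complexity": r.complexity,
            "n_entities": r.n_entities, "n_relations": r.n_relations,
        }
        for r in records
    ]
    return pd.DataFrame.from_records(rows).sort_values(["model", "doc_id"]).reset_index(drop=True)


def correlation_report(records: Iterable[DocumentRecord]) -> dict[str, dict]:
    """Per-model correlation analysis over document-level observations.

    For every model: the accuracy–consistency association under all three
    tests, K–S normality checks of both score distributions, and the
    pairwise Spearman matrix over accuracy, consistency, document length and
    the complexity covariates.  A variable with zero variance (e.g. every
    document perfectly consistent) yields ``None`` entries for the tests it
    invalidates rather than an error, so one degenerate model does not sink
    the report.
    """
    df = records_frame(records)
    if df.empty:
        raise ValueError("correlation_report: no records")
    report: dict[str, dict] = {}
    for model, g in df.groupby("model", sort=True):
        if len(g) < 3:
            raise ValueError(f"correlation_report: model {model!r} has {len(g)} < 3 documents")
        entry: dict = {"n_documents": int(len(g))}
        acc = g["accuracy"].to_numpy()
        cons = g["consistency"].to_numpy()
        tests = {}
        for method in ("pearson", "spearman", "kendall"):
            try:
                res = correlate(acc, cons, method)
                tests[method] = {"coefficient": res.coefficient, "p_value": res.p_value, "n": res.n}
            except ValueError:
                tests[method] = None
        entry["accuracy_vs_consistency"] = tests
        normality = {}
        for name, vals in (("accuracy", acc), ("consistency", cons)):
            try:
                stat, p, ok = ks_normality(vals)
                normality[name] = {"statistic": stat, "p_value": p, "passes": ok}
            except ValueError:
                normality[name] = None
        entry["ks_normality"] = normality
        sub = g[list(COVARIATE_COLUMNS)]
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = sub.corr(method="spearman")
        entry["spearman_matrix"] = rho
        report[str(model)] = entry
    return report
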