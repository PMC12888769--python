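"""Run-to-run consistency of repeated generations, measured with Fleiss' kappa.

The repeated generations of one model on one document are treated as raters
and every unique predicted relation triplet appearing across the well-formed
runs as a subject.  Each subject receives a binary rating per run — present
or absent — yielding an N x 2 rating matrix.  Consistency is the
chance-corrected agreement

    kappa = (P_bar - P_e) / (1 - P_e)

with per-subject agreement ``P_i = sum_j n_ij (n_ij - 1) / (n (n - 1))``,
``P_bar`` their mean, and chance agreement ``P_e = sum_j p_j^2`` from the
marginal category proportions.

Triplet identity is deliberately *strict* — raw strings with only
leading/trailing whitespace trimmed, no case folding and no
semantic-equivalence mapping — because consistency is meant to be usable as
an inference-time proxy that never consults the gold annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from docre_eval.corpus import normalize_form
from docre_eval.repair import ParsedRun

__all__ = ["RatingMatrix", "KappaResult", "build_rating_matrix", "fleiss_kappa", "macro_average_consistency"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatingMatrix:
    """N x 2 presence/absence counts for unique triplets over n runs."""

    subjects: tuple[tuple[str, str, str], ...]
    n_runs: int
    cells: tuple[tuple[int, int], ...]  # (count present, count absent) per subject

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValueError("rating matrix needs n >= 2 runs")
        if len(self.cells) != len(self.subjects):
            raise ValueError("one cell pair per subject required")
        for present, absent in self.cells:
            if present < 0 or absent < 0 or present + absent != self.n_runs:
                raise ValueError(f"cell ({present}, {absent}) does not sum to n = {self.n_runs}")

    @property
    def N(self) -> int:
        return len(self.subjects)


@dataclass(frozen=True)
class KappaResult:
    """Fleiss' kappa with its components; ``degenerate`` flags the no-variation cases."""

    kappa: float
    p_bar: float
    p_e: float
    N: int
    n: int
    degenerate: bool


def _canon_triplet(source: str, type_: str, target: str, fold: bool) -> tuple[str, str, str]:
    if fold:
        return (normalize_form(source), normalize_form(type_), normalize_form(target))
    return (source.strip(), type_.strip(), target.strip())


def build_rating_matrix(runs: Sequence[ParsedRun], normalize_subjects: bool = False) -> RatingMatrix:
    """Build the presence/absence matrix over the well-formed runs of one (model, doc).

    Duplicate triplets within one run collapse (presence is binary); a
    well-formed run with an empty extraction still rates every subject as
    absent.  ``normalize_subjects`` switches the subject identity from strict
    strings to normalized forms, for sensitivity analyses only.
    """
    wellformed = [r for r in runs if r.status != "unrecoverable"]
    if len(wellformed) < 2:
        raise ValueError(f"build_rating_matrix: need >= 2 well-formed runs, got {len(wellformed)}")
    keys = {(r.model, r.doc_id) for r in wellformed}
    if len(keys) != 1:
        raise ValueError(f"build_rating_matrix: runs span several (model, doc) pairs: {keys}")
    n = len(wellformed)
    per_run_sets = [
        {_canon_triplet(p.source, p.type, p.target, normalize_subjects) for p in r.relations}
        for r in wellformed
    ]
    subjects = sorted(set().union(*per_run_sets))
    cells = []
    for s in subjects:
        present = sum(1 for rs in per_run_sets if s in rs)
        cells.append((present, n - present))
    return RatingMatrix(subjects=tuple(subjects), n_runs=n, cells=tuple(cells))


def fleiss_kappa(m: RatingMatrix) -> KappaResult:
    """Fleiss' kappa of a presence/absence rating matrix.

    Degenerate cases of the presence/absence construction: with no subjects
    at all (every run empty), or with every subject present in every run
    (chance agreement P_e = 1), observed agreement is perfect and kappa is
    defined as 1 with ``degenerate=True``.
    """
    n = m.n_runs
    N = m.N
    if N == 0:
        return KappaResult(kappa=1.0, p_bar=1.0, p_e=1.0, N=0, n=n, degenerate=True)
    p_i = [(pres * (pres - 1) + absent * (absent - 1)) / (n * (n - 1)) for pres, absent in m.cells]
    p_bar = sum(p_i) / N
    total = N * n
    p_present = sum(pres for pres, _ in m.cells) / total
    p_e = p_present**2 + (1.0 - p_present) ** 2
    if p_e >= 1.0:
        # only reachable when every subject got the same rating from every run,
        # which for this construction means present in all runs (absent subjects
        # are never enumerated); observed agreement is then perfect too
        assert p_bar == 1.0, "P_e = 1 with imperfect agreement cannot arise from presence/absence data"
        return KappaResult(kappa=1.0, p_bar=p_bar, p_e=p_e, N=N, n=n, degenerate=True)
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(kappa=kappa, p_bar=p_bar, p_e=p_e, N=N, n=n, degenerate=False)


def macro_average_consistency(results: Iterable[KappaResult]) -> float:
    """Unweighted mean kappa over documents (the model's macro consistency)."""
    results = list(results)
    if not results:
        raise ValueError("macro_average_consistency: empty result collection")
    return sum(r.kappa for r in results) / len(results)
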