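"""Covariates, normality checks and correlation tests."""

import itertools
import math

import numpy as np
import pytest

from docre_eval.corpus import AnnotatedDocument, EntityMention, Span, TextBoundRelation
from docre_eval.stats import (
    DocumentRecord,
    correlate,
    correlation_report,
    document_metrics,
    ks_normality,
)


class TestDocumentMetrics:
    def test_small_document(self):
        doc = AnnotatedDocument(
            doc_id="d", text="abc",
            mentions=[EntityMention("T1", "Pest", (Span(0, 1),), "a"),
                      EntityMention("T2", "Plant", (Span(1, 2),), "b")],
            relations=[TextBoundRelation("R1", "Has been found on", "T1", "T2")],
        )
        assert document_metrics(doc) == (3, 2, 1, 3)

    def test_length_is_utf8_bytes(self):
        doc = AnnotatedDocument(doc_id="d", text="é")
        assert document_metrics(doc)[0] == 2

    def test_empty_document(self):
        assert document_metrics(AnnotatedDocument(doc_id="d", text="")) == (0, 0, 0, 0)


class TestKSNormality:
    def test_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        stat, p, passes = ks_normality(rng.normal(0.5, 0.1, size=200))
        assert passes

    def test_extreme_bimodal_fails(self):
        rng = np.random.default_rng(0)
        values = (rng.uniform(size=200) > 0.5).astype(float)
        stat, p, passes = ks_normality(values)
        assert not passes

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero-variance|degenerate"):
            ks_normality([0.5] * 20)

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            ks_normality([0.1, 0.2, 0.3])


class TestCorrelate:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 5.0, 7.0, 11.0]
        y = [2 * v + 1 for v in x]
        assert correlate(x, y, "pearson").coefficient == pytest.approx(1.0)

    def test_perfect_antimonotone_spearman(self):
        r = correlate([1, 2, 3], [3, 2, 1], "spearman")
        assert r.coefficient == pytest.approx(-1.0)

    def test_kendall_tau_b_against_permutation_oracle(self):
        x = [1, 2, 3, 4]
        y = [1, 3, 2, 4]
        r = correlate(x, y, "kendall")
        assert r.coefficient == pytest.approx(2 / 3)

        def tau(a, b):
            s = 0
            for i, j in itertools.combinations(range(len(a)), 2):
                s += np.sign(a[i] - a[j]) * np.sign(b[i] - b[j])
            return s / math.comb(len(a), 2)

        observed = tau(x, y)
        taus = [tau(x, list(perm)) for perm in itertools.permutations(y)]
        p_exact = sum(1 for t in taus if abs(t) >= abs(observed) - 1e-12) / len(taus)
        assert r.p_value == pytest.approx(p_exact, abs=1e-12)

    def test_self_correlation_is_one_for_all_methods(self):
        x = [0.3, 0.1, 0.9, 0.5, 0.7]
        for method in ("pearson", "spearman", "kendall"):
            assert correlate(x, x, method).coefficient == pytest.approx(1.0)

    def test_rank_methods_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=30)
        y = rng.uniform(size=30)
        for method in ("spearman", "kendall"):
            base = correlate(x, y, method).coefficient
            assert correlate(np.exp(3 * x), y, method).coefficient == pytest.approx(base)
            assert correlate(x, y**3, method).coefficient == pytest.approx(base)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate([1, 1, 1], [1, 2, 3])

    def test_pearson_p_value_agrees_with_permutation_test(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        r = correlate(x, y, "pearson")
        obs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= obs
        p_mc = count / n_perm
        mc_err = 3 * np.sqrt(max(p_mc, r.p_value) * (1 - min(p_mc, r.p_value)) / n_perm) + 1e-3
        assert abs(p_mc - r.p_value) < mc_err + 0.01


def _records(model, accs, cons, seed=0):
    rng = np.random.default_rng(seed)
    return [
        DocumentRecord(model=model, doc_id=f"d{i}", accuracy=a, consistency=c,
                       length_bytes=int(rng.integers(200, 2000)),
                       n_entities=int(rng.integers(2, 30)), n_relations=int(rng.integers(1, 15)))
        for i, (a, c) in enumerate(zip(accs, cons))
    ]


class TestCorrelationReport:
    def test_coupled_scores_show_positive_association(self):
        rng = np.random.default_rng(4)
        latent = rng.uniform(size=60)
        accs = np.clip(latent + rng.normal(0, 0.1, 60), 0, 1)
        cons = np.clip(latent + rng.normal(0, 0.1, 60), 0, 1)
        rep = correlation_report(_records("m", accs, cons))
        sp = rep["m"]["accuracy_vs_consistency"]["spearman"]
        assert sp["coefficient"] > 0
        assert sp["p_value"] < 0.05

    def test_independent_scores_inside_null_band(self):
        rng = np.random.default_rng(5)
        accs = rng.uniform(size=150)
        cons = rng.uniform(size=150)
        rep = correlation_report(_records("m", accs, cons))
        sp = rep["m"]["accuracy_vs_consistency"]["spearman"]
        assert abs(sp["coefficient"]) < 1.96 / np.sqrt(149)

    def test_identical_inputs_give_identical_reports(self):
        recs = _records("m", [0.2, 0.4, 0.6, 0.8], [0.1, 0.5, 0.3, 0.9])
        r1 = correlation_report(recs)
        r2 = correlation_report(list(recs))
        assert r1["m"]["accuracy_vs_consistency"] == r2["m"]["accuracy_vs_consistency"]
        assert r1["m"]["spearman_matrix"].equals(r2["m"]["spearman_matrix"])

    def test_spearman_matrix_covers_all_covariates(self):
        rng = np.random.default_rng(6)
        recs = _records("m", rng.uniform(size=20), rng.uniform(size=20))
        mat = correlation_report(recs)["m"]["spearman_matrix"]
        assert set(mat.columns) == {"accuracy", "consistency", "length_bytes",
                                    "complexity", "n_entities", "n_relations"}

    def test_too_few_documents_errors(self):
        with pytest.raises(ValueError, match="< 3"):
            correlation_report(_records("m", [0.1, 0.2], [0.3, 0.4]))
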