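"""Corpus model: normalization, dialect readers, structural and schema validation."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from docre_eval.corpus import (
    AnnotatedDocument,
    CorpusParseError,
    CorpusSchemaError,
    CorpusValidationError,
    EntityMention,
    Span,
    TextBoundRelation,
    normalize_form,
    read_corpus,
    validate_schema,
    write_corpus,
)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Japanese  Beetles ", "japanese beetles"),
        ("", ""),
        ("Bactrocera\tDORSALIS", "bactrocera dorsalis"),
        ("  Foc\n", "foc"),
        ("STRASSE", "strasse"),  # full case folding, not plain lowercasing
    ],
)
def test_normalize_form_examples(raw, expected):
    assert normalize_form(raw) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(max_size=60))
def test_normalize_form_idempotent(s):
    assert normalize_form(normalize_form(s)) == normalize_form(s)


def test_roundtrip_canonical_json(banana_doc, tmp_path):
    write_corpus([banana_doc], tmp_path / "corpus")
    docs = read_corpus(tmp_path / "corpus")
    assert len(docs) == 1
    d = docs[0]
    assert d.doc_id == banana_doc.doc_id
    assert d.text == banana_doc.text
    assert d.mentions == banana_doc.mentions
    assert sorted(c.member_ids for c in d.coref_sets) == sorted(c.member_ids for c in banana_doc.coref_sets)
    assert d.relations == banana_doc.relations


def test_coreferent_mentions_resolve_to_same_set(banana_doc):
    sets_with_t1 = [c for c in banana_doc.coref_sets if "T1" in c.member_ids]
    sets_with_t4 = [c for c in banana_doc.coref_sets if "T4" in c.member_ids]
    assert sets_with_t1 == sets_with_t4 and len(sets_with_t1) == 1


def test_standoff_reader(tmp_path):
    text = "Popillia japonica was observed in Freiburg. Japanese beetles spread."
    (tmp_path / "doc1.txt").write_text(text, encoding="utf-8")
    (tmp_path / "doc1.ann").write_text(
        "T1\tPest 0 17\tPopillia japonica\n"
        "T2\tLocation 34 42\tFreiburg\n"
        "T3\tPest 44 60\tJapanese beetles\n"
        "N1\tReference T1 NCBI_Taxonomy:7064\n"
        "N2\tReference T3 NCBI_Taxonomy:7064\n"
        "*\tCoreference T1 T3\n"
        "R1\tLocated in Arg1:T1 Arg2:T2\n",
        encoding="utf-8",
    )
    docs = read_corpus(tmp_path, dialect="standoff")
    assert len(docs) == 1
    d = docs[0]
    assert {m.id for m in d.mentions} == {"T1", "T2", "T3"}
    assert d.mention("T1").normalization == ("NCBI_Taxonomy", "7064")
    assert d.coref_sets[0].member_ids == {"T1", "T3"}
    assert d.relations[0].type == "Located in"


def test_standoff_discontinuous_mention(tmp_path):
    text = "citrus trees and greening observed."
    (tmp_path / "d.txt").write_text(text, encoding="utf-8")
    (tmp_path / "d.ann").write_text("T1\tDisease 0 6;17 25\tcitrus greening\n", encoding="utf-8")
    [doc] = read_corpus(tmp_path, dialect="standoff")
    assert doc.mention("T1").surface_form == "citrus greening"
    assert len(doc.mention("T1").spans) == 2


def test_dangling_relation_rejected(tmp_path):
    obj = {"doc_id": "d", "text": "x y", "entities": [], "corefs": [],
           "relations": [{"id": "R1", "type": "Causes", "source": "T9", "target": "T8"}]}
    (tmp_path / "d.json").write_text(json.dumps(obj), encoding="utf-8")
    with pytest.raises(CorpusValidationError, match="unknown mention"):
        read_corpus(tmp_path)


def test_span_outside_text_rejected(tmp_path):
    obj = {"doc_id": "d", "text": "ab",
           "entities": [{"id": "T1", "type": "Pest", "spans": [[0, 9]], "form": "ab", "norm": None}],
           "corefs": [], "relations": []}
    (tmp_path / "d.json").write_text(json.dumps(obj), encoding="utf-8")
    with pytest.raises(CorpusValidationError, match="outside text"):
        read_corpus(tmp_path)


def test_unknown_entity_type_rejected(tmp_path):
    obj = {"doc_id": "d", "text": "ab",
           "entities": [{"id": "T1", "type": "Dragon", "spans": [[0, 2]], "form": "ab", "norm": None}],
           "corefs": [], "relations": []}
    (tmp_path / "d.json").write_text(json.dumps(obj), encoding="utf-8")
    with pytest.raises(CorpusSchemaError, match="Dragon"):
        read_corpus(tmp_path)


def test_malformed_json_names_file(tmp_path):
    (tmp_path / "bad.json").write_text("{not json", encoding="utf-8")
    with pytest.raises(CorpusParseError, match="bad.json"):
        read_corpus(tmp_path)


def test_surface_form_must_match_spans():
    with pytest.raises(CorpusValidationError, match="surface form"):
        AnnotatedDocument(
            doc_id="d", text="abcdef",
            mentions=[EntityMention("T1", "Pest", (Span(0, 3),), "xyz")],
        ).validate()


class TestValidateSchema:
    def test_conformant_relation(self):
        doc = AnnotatedDocument(
            doc_id="d", text="aphid blight",
            mentions=[
                EntityMention("T1", "Pest", (Span(0, 5),), "aphid"),
                EntityMention("T2", "Disease", (Span(6, 12),), "blight"),
            ],
            relations=[TextBoundRelation("R1", "Causes", "T1", "T2")],
        )
        doc.validate()
        assert validate_schema(doc) == []

    def test_transmits_with_disease_source_violates(self):
        doc = AnnotatedDocument(
            doc_id="d", text="blight vine",
            mentions=[
                EntityMention("T1", "Disease", (Span(0, 6),), "blight"),
                EntityMention("T2", "Plant", (Span(7, 11),), "vine"),
            ],
            relations=[TextBoundRelation("R1", "Transmits", "T1", "T2")],
        )
        doc.validate()
        violations = validate_schema(doc)
        assert len(violations) == 2  # Transmits wants a Vector source and a Pest/Disease target
        roles = {v.role for v in violations}
        assert roles == {"source", "target"}
        src = next(v for v in violations if v.role == "source")
        assert src.allowed_types == frozenset({"Vector"})

    def test_empty_document(self):
        doc = AnnotatedDocument(doc_id="d", text="")
        assert validate_schema(doc) == []
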