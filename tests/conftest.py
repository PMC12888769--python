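import pytest

from docre_eval.corpus import (
    AnnotatedDocument,
    CoreferenceSet,
    EntityMention,
    Span,
    TextBoundRelation,
)


@pytest.fixture
def banana_doc() -> AnnotatedDocument:
    """Handmade document with a coreference set, normalization links and a duplicate relation.

    The pathogen appears under its full name and its acronym (one coreference
    set, shared taxonomy identifier); the fruit fly appears under scientific
    and common name linked only through the taxonomy identifier (no coref
    line).  Two text-bound Causes relations express the same fact through the
    two coreferent pathogen mentions.
    """
    text = (
        "Fusarium oxysporum f. sp. Cubense fungi causes fusariosis in banana. "
        "Foc causes fusariosis. "
        "Bactrocera dorsalis was observed in Freiburg. "
        "The oriental fruitfly damages fruit."
    )

    def mention(mid, etype, surface, norm=None, start=None):
        start = text.index(surface) if start is None else start
        return EntityMention(
            id=mid, type=etype, spans=(Span(start, start + len(surface)),),
            surface_form=surface, normalization=norm,
        )

    doc = AnnotatedDocument(
        doc_id="100011",
        text=text,
        mentions=[
            mention("T1", "Pest", "Fusarium oxysporum f. sp. Cubense fungi", ("NCBI_Taxonomy", "61366")),
            mention("T2", "Disease", "fusariosis"),
            mention("T3", "Plant", "banana"),
            mention("T4", "Pest", "Foc", ("NCBI_Taxonomy", "61366")),
            mention("T5", "Disease", "fusariosis", None, text.index("fusariosis", 50)),
            mention("T6", "Pest", "Bactrocera dorsalis", ("NCBI_Taxonomy", "27457")),
            mention("T7", "Location", "Freiburg", ("GeoNames", "2925177")),
            mention("T8", "Pest", "oriental fruitfly", ("NCBI_Taxonomy", "27457")),
        ],
        coref_sets=[
            CoreferenceSet(id="C1", member_ids=frozenset({"T1", "T4"})),
            CoreferenceSet(id="C2", member_ids=frozenset({"T2", "T5"})),
        ],
        relations=[
            TextBoundRelation(id="R1", type="Causes", source_id="T1", target_id="T2"),
            TextBoundRelation(id="R2", type="Causes", source_id="T4", target_id="T5"),
            TextBoundRelation(id="R3", type="Affects", source_id="T2", target_id="T3"),
            TextBoundRelation(id="R4", type="Located in", source_id="T6", target_id="T7"),
        ],
    )
    doc.validate()
    return doc
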