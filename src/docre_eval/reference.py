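"""Build the document-level relation-extraction reference from text-bound annotations.

The reference for one document is derived in three steps:

1. collect every text-bound relation of the document;
2. replace each relation argument by its *acceptable-form set* — the
   case-folded, space-normalized surface forms of every mention of the
   document that is reachable from the argument mention through coreference
   links or through a shared entity-linking class identifier (connected
   components over both link kinds); in strict mode the set is just the
   singleton normalized form of the argument mention itself;
3. collapse duplicates — two relations are duplicates when they share the
   relation type and have identical source and target form sets.

Step 2 is what makes the evaluation tolerant to *recoverable* surface
variation (a scientific name vs. its acronym or common name); the strict
variant measures the cost of ignoring it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from docre_eval.corpus import AnnotatedDocument, EntityMention, normalize_form

__all__ = [
    "ArgumentFormSet",
    "DocRERelation",
    "DocREReference",
    "collect_acceptable_forms",
    "build_docre_reference",
    "count_reference",
    "write_reference",
    "read_reference",
]


@dataclass(frozen=True)
class ArgumentFormSet:
    """Normalized surface forms acceptable for one relation argument."""

    forms: frozenset[str]
    entity_type: str
    provenance: frozenset[str]  # contributing mention ids

    def __post_init__(self) -> None:
        if not self.forms:
            raise ValueError("empty argument form set")


@dataclass(frozen=True)
class DocRERelation:
    """One document-level relation with acceptable-form argument sets."""

    doc_id: str
    type: str
    source: ArgumentFormSet
    target: ArgumentFormSet
    #: ids of the text-bound relations this document-level relation aggregates
    provenance: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, frozenset[str], frozenset[str]]:
        """Duplicate-collapsing identity: (type, source forms, target forms)."""
        return (self.type, self.source.forms, self.target.forms)


@dataclass
class DocREReference:
    """The deduplicated document-level reference for one document."""

    doc_id: str
    relations: list[DocRERelation] = field(default_factory=list)


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _equivalence_components(doc: AnnotatedDocument) -> dict[str, list[EntityMention]]:
    """Map each mention id to its semantic-equivalence component.

    Components are connected components over two link kinds: membership in a
    common coreference set, and a shared (resource, class_id) normalization.
    """
    uf = _UnionFind()
    for m in doc.mentions:
        uf.find(m.id)
    for cs in doc.coref_sets:
        members = sorted(cs.member_ids)
        for other in members[1:]:
            uf.union(members[0], other)
    by_norm: dict[tuple[str, str], list[str]] = {}
    for m in doc.mentions:
        if m.normalization is not None:
            by_norm.setdefault(m.normalization, []).append(m.id)
    for ids in by_norm.values():
        ids.sort()
        for other in ids[1:]:
            uf.union(ids[0], other)
    comps: dict[str, list[EntityMention]] = {}
    for m in doc.mentions:
        comps.setdefault(uf.find(m.id), []).append(m)
    return {m.id: comps[uf.find(m.id)] for m in doc.mentions}


def collect_acceptable_forms(mention: EntityMention, doc: AnnotatedDocument) -> ArgumentFormSet:
    """Acceptable-form set for one mention: itself plus coreferent and co-normalized mentions."""
    comp = _equivalence_components(doc)[mention.id]
    return ArgumentFormSet(
        forms=frozenset(normalize_form(m.surface_form) for m in comp),
        entity_type=mention.type,
        provenance=frozenset(m.id for m in comp),
    )


def build_docre_reference(doc: AnnotatedDocument, use_equivalence: bool = True) -> DocREReference:
    """Aggregate a document's text-bound relations into the DocRE reference.

    With ``use_equivalence`` each argument is replaced by its acceptable-form
    set; without it, by the singleton normalized surface form of the argument
    mention (string normalization is applied in both modes).  Relations that
    share type and both form sets collapse to one; the result is independent
    of the input annotation order.
    """
    by_id = {m.id: m for m in doc.mentions}
    comps = _equivalence_components(doc) if use_equivalence else None

    def argset(mention_id: str) -> ArgumentFormSet:
        m = by_id[mention_id]
        if comps is None:
            return ArgumentFormSet(
                forms=frozenset({normalize_form(m.surface_form)}),
                entity_type=m.type,
                provenance=frozenset({m.id}),
            )
        comp = comps[mention_id]
        return ArgumentFormSet(
            forms=frozenset(normalize_form(x.surface_form) for x in comp),
            entity_type=m.type,
            provenance=frozenset(x.id for x in comp),
        )

    merged: dict[tuple, DocRERelation] = {}
    for r in doc.relations:
        rel = DocRERelation(
            doc_id=doc.doc_id,
            type=r.type,
            source=argset(r.source_id),
            target=argset(r.target_id),
            provenance=frozenset({r.id}),
        )
        prev = merged.get(rel.key)
        if prev is not None:
            rel = DocRERelation(
                doc_id=doc.doc_id,
                type=rel.type,
                source=rel.source,
                target=rel.target,
                provenance=prev.provenance | rel.provenance,
            )
        merged[rel.key] = rel
    relations = sorted(
        merged.values(),
        key=lambda x: (x.type, sorted(x.source.forms), sorted(x.target.forms)),
    )
    return DocREReference(doc_id=doc.doc_id, relations=relations)


def count_reference(refs: Iterable[DocREReference]) -> tuple[int, int]:
    """Corpus-level counts: (total relations, relations with a multi-form argument)."""
    total = 0
    multi = 0
    for ref in refs:
        for rel in ref.relations:
            total += 1
            if len(rel.source.forms) >= 2 or len(rel.target.forms) >= 2:
                multi += 1
    return total, multi


def _ref_to_json(ref: DocREReference) -> dict:
    return {
        "doc_id": ref.doc_id,
        "relations": [
            {
                "type": rel.type,
                "source_forms": sorted(rel.source.forms),
                "source_type": rel.source.entity_type,
                "target_forms": sorted(rel.target.forms),
                "target_type": rel.target.entity_type,
                "provenance": sorted(rel.provenance),
            }
            for rel in ref.relations
        ],
    }


def write_reference(refs: Sequence[DocREReference], path: str | Path) -> None:
    """Write references as a single JSON list with sorted form lists (byte-stable)."""
    payload = [_ref_to_json(r) for r in sorted(refs, key=lambda r: r.doc_id)]
    Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1) + "\n", encoding="utf-8")


def read_reference(path: str | Path) -> list[DocREReference]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for obj in payload:
        rels = [
            DocRERelation(
                doc_id=obj["doc_id"],
                type=r["type"],
                source=ArgumentFormSet(frozenset(r["source_forms"]), r["source_type"], frozenset(r.get("provenance", []))),
                target=ArgumentFormSet(frozenset(r["target_forms"]), r["target_type"], frozenset(r.get("provenance", []))),
                provenance=frozenset(r.get("provenance", [])),
            )
            for r in obj["relations"]
        ]
        out.append(DocREReference(doc_id=obj["doc_id"], relations=rels))
    return out
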