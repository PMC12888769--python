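"""Domain model and readers for text-bound relation-extraction corpora.

The annotation schema is the five-type plant-health schema used by the EPOP
epidemiomonitoring corpus: entity types Disease, Location, Pest, Plant and
Vector; binary relation types Causes, Affects, "Has been found on",
"Located in" and Transmits, each with strict argument-type constraints.
Documents carry typed entity mentions with character spans (possibly
discontinuous), coreference sets grouping mentions of the same real-world
entity, entity-linking normalizations (NCBI Taxonomy, GeoNames) and
text-bound binary relations between mentions.

Two interchange dialects are supported:

``canonical-json``
    One JSON object per document (or a JSON list of such objects)::

        {"doc_id": ..., "text": ...,
         "entities":  [{"id","type","spans":[[start,end],...],"form",
                        "norm":{"resource","class_id"}|null}, ...],
         "corefs":    [{"id","members":[...]}, ...],
         "relations": [{"id","type","source","target"}, ...]}

``standoff``
    BioNLP-ST-like: per document a ``<doc_id>.txt`` with the raw text and a
    ``<doc_id>.ann`` with one annotation per line —
    ``T<n>\\t<Type> <start> <end>[;<start> <end>...]\\t<surface>`` for
    mentions, ``N<n>\\tReference T<k> <resource>:<class_id>`` for
    normalizations, ``*\\tCoreference T<i> T<j> ...`` for coreference sets and
    ``R<n>\\t<Type> Arg1:T<i> Arg2:T<j>`` for relations.

Offsets are 0-based, half-open, over Unicode code points.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "ENTITY_TYPES",
    "RELATION_TYPES",
    "RELATION_CONSTRAINTS",
    "Span",
    "EntityMention",
    "CoreferenceSet",
    "TextBoundRelation",
    "AnnotatedDocument",
    "SchemaViolation",
    "CorpusError",
    "CorpusParseError",
    "CorpusValidationError",
    "CorpusSchemaError",
    "normalize_form",
    "read_corpus",
    "write_corpus",
    "validate_schema",
]

#: Closed enumeration of entity types.
ENTITY_TYPES: tuple[str, ...] = ("Disease", "Location", "Pest", "Plant", "Vector")

#: Argument-type constraints per relation type: label -> (allowed sources, allowed targets).
RELATION_CONSTRAINTS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "Causes": (frozenset({"Pest"}), frozenset({"Disease"})),
    "Affects": (frozenset({"Disease"}), frozenset({"Plant"})),
    "Has been found on": (frozenset({"Pest", "Vector"}), frozenset({"Vector", "Plant"})),
    "Located in": (frozenset({"Pest", "Plant", "Vector"}), frozenset({"Location"})),
    "Transmits": (frozenset({"Vector"}), frozenset({"Pest", "Disease"})),
}

RELATION_TYPES: tuple[str, ...] = tuple(RELATION_CONSTRAINTS)


class CorpusError(Exception):
    """Base class for corpus reading/validation failures."""


class CorpusParseError(CorpusError):
    """A file could not be parsed; the message names the file (and line where known)."""


class CorpusValidationError(CorpusError):
    """Structurally parseable input violating a document invariant (spans, ids)."""


class CorpusSchemaError(CorpusError):
    """Unknown entity or relation type label."""


def normalize_form(s: str) -> str:
    """Normalize an entity surface form for comparison.

    Applies full Unicode case folding and collapses every whitespace run to a
    single space, stripping leading/trailing whitespace.  Idempotent.
    """
    return " ".join(s.casefold().split())


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval ``[start, end)`` over code points."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(f"invalid span [{self.start}, {self.end})")


@dataclass(frozen=True)
class EntityMention:
    """A typed, text-bound entity mention.

    ``spans`` is ordered and non-overlapping; more than one span encodes a
    discontinuous mention.  ``surface_form`` must equal the span texts joined
    by a single space.  ``normalization`` is an optional
    ``(resource, class_id)`` entity-linking pair (e.g. ``("NCBI_Taxonomy",
    "27457")``).
    """

    id: str
    type: str
    spans: tuple[Span, ...]
    surface_form: str
    normalization: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.type not in ENTITY_TYPES:
            raise CorpusSchemaError(f"unknown entity type {self.type!r} (mention {self.id})")
        if not self.spans:
            raise CorpusValidationError(f"mention {self.id} has no spans")
        for a, b in zip(self.spans, self.spans[1:]):
            if b.start < a.end:
                raise CorpusValidationError(f"mention {self.id} spans overlap or are unordered")


@dataclass(frozen=True)
class CoreferenceSet:
    """Mentions of one document referring to the same real-world entity."""

    id: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise CorpusValidationError(f"coreference set {self.id} needs >= 2 members")


@dataclass(frozen=True)
class TextBoundRelation:
    """A typed binary relation between two mentions of the same document."""

    id: str
    type: str
    source_id: str
    target_id: str

    def __post_init__(self) -> None:
        if self.type not in RELATION_CONSTRAINTS:
            raise CorpusSchemaError(f"unknown relation type {self.type!r} (relation {self.id})")


@dataclass
class AnnotatedDocument:
    """A document with its text-bound annotation layers."""

    doc_id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)
    coref_sets: list[CoreferenceSet] = field(default_factory=list)
    relations: list[TextBoundRelation] = field(default_factory=list)

    def mention(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.id == mention_id:
                return m
        raise KeyError(mention_id)

    def validate(self) -> None:
        """Check all structural invariants, raising :class:`CorpusValidationError`.

        Verified: id uniqueness across layers, spans inside the text, surface
        forms matching span texts, resolvable coreference members and relation
        arguments, and type/identifier homogeneity inside coreference sets.
        """
        ids: set[str] = set()
        for layer in (self.mentions, self.coref_sets, self.relations):
            for item in layer:  # type: ignore[attr-defined]
                if item.id in ids:
                    raise CorpusValidationError(f"{self.doc_id}: duplicate id {item.id!r}")
                ids.add(item.id)
        by_id = {m.id: m for m in self.mentions}
        n = len(self.text)
        for m in self.mentions:
            for sp in m.spans:
                if sp.end > n:
                    raise CorpusValidationError(
                        f"{self.doc_id}: mention {m.id} span [{sp.start},{sp.end}) outside text of length {n}"
                    )
            joined = " ".join(self.text[sp.start:sp.end] for sp in m.spans)
            if m.surface_form != joined:
                raise CorpusValidationError(
                    f"{self.doc_id}: mention {m.id} surface form {m.surface_form!r} "
                    f"does not match span text {joined!r}"
                )
        for cs in self.coref_sets:
            members = []
            for mid in cs.member_ids:
                if mid not in by_id:
                    raise CorpusValidationError(f"{self.doc_id}: coref set {cs.id} names unknown mention {mid!r}")
                members.append(by_id[mid])
            if len({m.type for m in members}) > 1:
                raise CorpusValidationError(f"{self.doc_id}: coref set {cs.id} mixes entity types")
            norms = {m.normalization for m in members if m.normalization is not None}
            if len(norms) > 1:
                raise CorpusValidationError(f"{self.doc_id}: coref set {cs.id} mixes class identifiers {norms}")
        for r in self.relations:
            for role, mid in (("source", r.source_id), ("target", r.target_id)):
                if mid not in by_id:
                    raise CorpusValidationError(
                        f"{self.doc_id}: relation {r.id} {role} names unknown mention {mid!r}"
                    )


@dataclass(frozen=True)
class SchemaViolation:
    """One relation whose argument types violate the schema constraints."""

    doc_id: str
    relation_id: str
    relation_type: str
    role: str  # "source" or "target"
    mention_id: str
    actual_type: str
    allowed_types: frozenset[str]


def validate_schema(doc: AnnotatedDocument) -> list[SchemaViolation]:
    """Report relations whose argument entity types break the constraint table.

    Report-only: a conformant document yields an empty list.  Assumes the
    document already passed structural validation.
    """
    by_id = {m.id: m for m in doc.mentions}
    out: list[SchemaViolation] = []
    for r in doc.relations:
        allowed_src, allowed_tgt = RELATION_CONSTRAINTS[r.type]
        for role, mid, allowed in (("source", r.source_id, allowed_src), ("target", r.target_id, allowed_tgt)):
            t = by_id[mid].type
            if t not in allowed:
                out.append(SchemaViolation(doc.doc_id, r.id, r.type, role, mid, t, allowed))
    return out


# ---------------------------------------------------------------------------
# canonical JSON dialect
# ---------------------------------------------------------------------------

def _doc_from_json(obj: dict, where: str) -> AnnotatedDocument:
    try:
        doc = AnnotatedDocument(doc_id=str(obj["doc_id"]), text=obj["text"])
        for e in obj.get("entities", []):
            norm = e.get("norm")
            doc.mentions.append(
                EntityMention(
                    id=str(e["id"]),
                    type=e["type"],
                    spans=tuple(Span(int(a), int(b)) for a, b in e["spans"]),
                    surface_form=e["form"],
                    normalization=(norm["resource"], str(norm["class_id"])) if norm else None,
                )
            )
        for c in obj.get("corefs", []):
            doc.coref_sets.append(CoreferenceSet(id=str(c["id"]), member_ids=frozenset(map(str, c["members"]))))
        for r in obj.get("relations", []):
            doc.relations.append(
                TextBoundRelation(id=str(r["id"]), type=r["type"], source_id=str(r["source"]), target_id=str(r["target"]))
            )
    except KeyError as exc:
        raise CorpusParseError(f"{where}: missing required key {exc}") from exc
    doc.validate()
    return doc


def _doc_to_json(doc: AnnotatedDocument) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "entities": [
            {
                "id": m.id,
                "type": m.type,
                "spans": [[sp.start, sp.end] for sp in m.spans],
                "form": m.surface_form,
                "norm": {"resource": m.normalization[0], "class_id": m.normalization[1]} if m.normalization else None,
            }
            for m in doc.mentions
        ],
        "corefs": [{"id": c.id, "members": sorted(c.member_ids)} for c in doc.coref_sets],
        "relations": [
            {"id": r.id, "type": r.type, "source": r.source_id, "target": r.target_id} for r in doc.relations
        ],
    }


# ---------------------------------------------------------------------------
# standoff dialect
# ---------------------------------------------------------------------------

_T_LINE = re.compile(r"^(T\S+)\t(\S+(?: \S+)*?) ((?:\d+ \d+)(?:;\d+ \d+)*)\t(.*)$")
_R_LINE = re.compile(r"^(R\S+)\t(.+?) Arg1:(T\S+) Arg2:(T\S+)\s*$")
_N_LINE = re.compile(r"^(N\S+)\tReference (T\S+) ([^:\s]+):(\S+)")
_C_LINE = re.compile(r"^\*\tCoreference ((?:T\S+\s*)+)$")


def _doc_from_standoff(txt_path: Path, ann_path: Path) -> AnnotatedDocument:
    text = txt_path.read_text(encoding="utf-8")
    doc = AnnotatedDocument(doc_id=txt_path.stem, text=text)
    norms: dict[str, tuple[str, str]] = {}
    raw_mentions: list[tuple[str, str, tuple[Span, ...], str]] = []
    coref_n = 0
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if m is None:
                raise CorpusParseError(f"{ann_path}:{lineno}: malformed mention line")
            tid, etype, offsets, surface = m.groups()
            spans = tuple(
                Span(int(a), int(b)) for a, b in (pair.split(" ") for pair in offsets.split(";"))
            )
            raw_mentions.append((tid, etype, spans, surface))
        elif line.startswith("R"):
            m = _R_LINE.match(line)
            if m is None:
                raise CorpusParseError(f"{ann_path}:{lineno}: malformed relation line")
            rid, rtype, src, tgt = m.groups()
            doc.relations.append(TextBoundRelation(id=rid, type=rtype, source_id=src, target_id=tgt))
        elif line.startswith("N"):
            m = _N_LINE.match(line)
            if m is None:
                raise CorpusParseError(f"{ann_path}:{lineno}: malformed normalization line")
            _, tid, resource, class_id = m.groups()
            norms[tid] = (resource, class_id)
        elif line.startswith("*"):
            m = _C_LINE.match(line)
            if m is None:
                raise CorpusParseError(f"{ann_path}:{lineno}: malformed coreference line")
            coref_n += 1
            members = frozenset(m.group(1).split())
            doc.coref_sets.append(CoreferenceSet(id=f"C{coref_n}", member_ids=members))
        else:
            raise CorpusParseError(f"{ann_path}:{lineno}: unrecognized annotation line {line[:40]!r}")
    for tid, etype, spans, surface in raw_mentions:
        doc.mentions.append(
            EntityMention(id=tid, type=etype, spans=spans, surface_form=surface, normalization=norms.get(tid))
        )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# public reader/writer
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, dialect: str = "canonical-json") -> list[AnnotatedDocument]:
    """Read a corpus directory or file, returning documents sorted by ``doc_id``.

    Parameters
    ----------
    path
        For ``canonical-json``: a ``.json`` file (one document object or a
        list of them) or a directory of such files.  For ``standoff``: a
        directory of paired ``<doc_id>.txt`` / ``<doc_id>.ann`` files.
    dialect
        ``"canonical-json"`` or ``"standoff"``.

    Every structural invariant is verified at read time; violations raise
    :class:`CorpusParseError`, :class:`CorpusValidationError` or
    :class:`CorpusSchemaError` naming the offending file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    docs: list[AnnotatedDocument] = []
    if dialect == "canonical-json":
        files = sorted(path.glob("*.json")) if path.is_dir() else [path]
        if not files:
            raise CorpusParseError(f"{path}: no .json files found")
        for f in files:
            try:
                payload = json.loads(f.read_text(encoding="utf-8"))
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"{f}:{exc.lineno}: invalid JSON: {exc.msg}") from exc
            objs = payload if isinstance(payload, list) else [payload]
            for obj in objs:
                docs.append(_doc_from_json(obj, str(f)))
    elif dialect == "standoff":
        txts = sorted(path.glob("*.txt"))
        if not txts:
            raise CorpusParseError(f"{path}: no .txt files found")
        for txt in txts:
            ann = txt.with_suffix(".ann")
            if not ann.exists():
                raise CorpusParseError(f"{ann}: missing annotation file for {txt.name}")
            docs.append(_doc_from_standoff(txt, ann))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    docs.sort(key=lambda d: d.doc_id)
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise CorpusValidationError(f"duplicate doc_id {d.doc_id!r} in corpus")
        seen.add(d.doc_id)
    return docs


def write_corpus(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write documents as one canonical-JSON file per document under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        out = path / f"{doc.doc_id}.json"
        out.write_text(json.dumps(_doc_to_json(doc), ensure_ascii=False, indent=1) + "\n", encoding="utf-8")
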