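"""Parse raw LLM generations into predicted relation triplets, repairing superficial JSON damage.

Generative models asked for a JSON object with ``"entities"`` and
``"relations"`` sections frequently wrap the payload in markdown fences or
prose, leave trailing commas, or stop before closing delimiters.  Those are
*format* errors, not extraction errors, so a bounded, content-preserving
repair is attempted before a run is discarded:

1. strip non-JSON framing — markdown code fences, prose before the first
   ``{``/``[`` and after the last ``}``/``]``;
2. delete trailing and duplicated commas (outside string literals);
3. close unmatched strings, brackets and braces at the end of the text.

The repair never reorders or rewrites values; it only deletes framing and
stray commas and appends closers.  Outputs that still do not parse are
marked ``unrecoverable`` and excluded from scoring and consistency.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RawRunOutput",
    "PredictedRelation",
    "ParsedRun",
    "repair_json",
    "parse_run",
    "tabulate_validity",
    "read_raw_runs",
    "write_raw_runs",
    "write_parsed_runs",
    "read_parsed_runs",
]

REQUIRED_KEYS = ("source", "type", "target")


@dataclass(frozen=True)
class RawRunOutput:
    """One raw generation: (model, document, run index) plus the output text."""

    model: str
    doc_id: str
    run_index: int
    text: str


@dataclass(frozen=True)
class PredictedRelation:
    """A predicted 〈source, type, target〉 triplet; fields kept verbatim."""

    source: str
    type: str
    target: str


@dataclass
class ParsedRun:
    """Outcome of parsing one generation.

    ``status`` is ``valid`` (strict parse), ``repaired`` (parse after
    superficial repair) or ``unrecoverable`` (excluded downstream).
    """

    key: tuple[str, str, int]
    relations: list[PredictedRelation] = field(default_factory=list)
    entity_section: object = None
    status: str = "valid"
    repair_log: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def model(self) -> str:
        return self.key[0]

    @property
    def doc_id(self) -> str:
        return self.key[1]

    @property
    def run_index(self) -> int:
        return self.key[2]


_FENCE = re.compile(r"```[a-zA-Z]*\n?|```")


def _strip_framing(text: str) -> str:
    text = _FENCE.sub("", text)
    starts = [i for i in (text.find("{"), text.find("[")) if i != -1]
    if not starts:
        return ""
    first = min(starts)
    last = max(text.rfind("}"), text.rfind("]"))
    if last < first:
        # no closing delimiter at all: keep the tail, closers are appended later
        return text[first:]
    return text[first : last + 1]


def _scan(text: str) -> tuple[list[str], bool]:
    """Return (open delimiter stack, in-string flag) after scanning ``text``."""
    stack: list[str] = []
    in_str = False
    escape = False
    for ch in text:
        if in_str:
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_str = False
            continue
        if ch == '"':
            in_str = True
        elif ch in "{[":
            stack.append(ch)
        elif ch == "}":
            if stack and stack[-1] == "{":
                stack.pop()
        elif ch == "]":
            if stack and stack[-1] == "[":
                stack.pop()
    return stack, in_str


def _drop_stray_commas(text: str) -> tuple[str, int]:
    """Remove commas directly followed (over whitespace) by ``}``, ``]`` or ``,``; string-aware."""
    out: list[str] = []
    removed = 0
    in_str = False
    escape = False
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if in_str:
            out.append(ch)
            if escape:
                escape = False
            elif ch == "\\":
                escape = True
            elif ch == '"':
                in_str = False
            i += 1
            continue
        if ch == '"':
            in_str = True
            out.append(ch)
            i += 1
            continue
        if ch == ",":
            j = i + 1
            while j < n and text[j].isspace():
                j += 1
            if j >= n or text[j] in "}],":
                removed += 1
                i += 1
                continue
        out.append(ch)
        i += 1
    return "".join(out), removed


def repair_json(text: str) -> tuple[str, list[str]]:
    """Best-effort superficial repair; returns the repaired text and the actions applied.

    Deterministic and idempotent on its own output; at most 3 passes.  Valid
    input comes back unchanged with an empty action list.
    """
    actions: list[str] = []
    current = text
    for _ in range(3):
        stripped = _strip_framing(current)
        if stripped != current:
            actions.append("strip_framing")
            current = stripped
        decommaed, n_commas = _drop_stray_commas(current)
        if n_commas:
            actions.append(f"remove_stray_commas:{n_commas}")
            current = decommaed
        stack, in_str = _scan(current)
        closers = ('"' if in_str else "") + "".join("}" if c == "{" else "]" for c in reversed(stack))
        if closers:
            actions.append(f"close_delimiters:{closers}")
            current = current + closers
        try:
            json.loads(current)
            break
        except json.JSONDecodeError:
            continue
    return current, actions


def _extract(payload: object, run: ParsedRun) -> bool:
    """Pull the relation triplets (and entity section) out of parsed JSON.

    Returns False when the payload has no JSON object/array structure to
    extract from (treated as unrecoverable by the caller).
    """
    if isinstance(payload, dict):
        run.entity_section = payload.get("entities")
        rel_items = payload.get("relations", [])
        if not isinstance(rel_items, list):
            run.warnings.append("relations section is not a list; treated as empty")
            rel_items = []
    elif isinstance(payload, list):
        # bare array: interpreted as the relations list
        rel_items = payload
    else:
        return False
    for i, item in enumerate(rel_items):
        if not isinstance(item, dict):
            run.warnings.append(f"relation {i}: not an object; dropped")
            continue
        values = {}
        ok = True
        for k in REQUIRED_KEYS:
            v = item.get(k)
            if not isinstance(v, str) or not v.strip():
                run.warnings.append(f"relation {i}: missing or empty {k!r}; dropped")
                ok = False
                break
            values[k] = v
        if ok:
            run.relations.append(PredictedRelation(values["source"], values["type"], values["target"]))
    return True


def parse_run(raw: RawRunOutput) -> ParsedRun:
    """Parse one generation: strict first, then after repair; relation types kept verbatim.

    A parseable object without a ``"relations"`` key is a *valid* run with an
    empty extraction (a semantic, not a format, failure).  Relation objects
    missing any of ``source``/``type``/``target`` are dropped with a warning.
    Duplicate identical triplets within a run are retained.
    """
    run = ParsedRun(key=(raw.model, raw.doc_id, raw.run_index))
    try:
        payload = json.loads(raw.text)
        status = "valid"
    except json.JSONDecodeError:
        repaired, actions = repair_json(raw.text)
        try:
            payload = json.loads(repaired)
        except json.JSONDecodeError:
            run.status = "unrecoverable"
            run.repair_log = actions
            return run
        status = "repaired" if actions else "valid"
        run.repair_log = actions
    if not _extract(payload, run):
        run.relations = []
        run.status = "unrecoverable"
        return run
    run.status = status
    return run


def tabulate_validity(runs: Iterable[ParsedRun]) -> pd.DataFrame:
    """Per-model proportions of recoverable errors, unrecoverable errors and valid outputs.

    ``valid`` is the proportion of outputs parseable after repair, i.e.
    ``1 - unrecoverable``; ``recoverable`` counts runs that needed repair.
    """
    rows: dict[str, dict[str, int]] = {}
    for r in runs:
        d = rows.setdefault(r.model, {"n": 0, "repaired": 0, "unrecoverable": 0})
        d["n"] += 1
        if r.status == "repaired":
            d["repaired"] += 1
        elif r.status == "unrecoverable":
            d["unrecoverable"] += 1
    if not rows:
        raise ValueError("tabulate_validity: no runs supplied")
    records = []
    for model in sorted(rows):
        d = rows[model]
        records.append(
            {
                "model": model,
                "n_runs": d["n"],
                "recoverable": d["repaired"] / d["n"],
                "unrecoverable": d["unrecoverable"] / d["n"],
                "valid": 1.0 - d["unrecoverable"] / d["n"],
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# file formats: JSON-Lines ensembles and per-run text trees
# ---------------------------------------------------------------------------

def write_raw_runs(runs: Sequence[RawRunOutput], path: str | Path) -> None:
    """Write an ensemble as JSON-Lines: one ``{"model","doc_id","run","output"}`` per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in sorted(runs, key=lambda r: (r.model, r.doc_id, r.run_index)):
            fh.write(json.dumps(
                {"model": r.model, "doc_id": r.doc_id, "run": r.run_index, "output": r.text},
                ensure_ascii=False) + "\n")


def read_raw_runs(path: str | Path) -> list[RawRunOutput]:
    """Read an ensemble from a JSON-Lines file, or from a ``<model>/<doc_id>/<run>.txt`` tree."""
    path = Path(path)
    runs: list[RawRunOutput] = []
    if path.is_dir():
        for f in sorted(path.glob("*/*/*.txt")):
            model, doc_id, run = f.parent.parent.name, f.parent.name, int(f.stem)
            runs.append(RawRunOutput(model, doc_id, run, f.read_text(encoding="utf-8")))
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                runs.append(RawRunOutput(obj["model"], obj["doc_id"], int(obj["run"]), obj["output"]))
    keys = [(r.model, r.doc_id, r.run_index) for r in runs]
    if len(keys) != len(set(keys)):
        raise ValueError(f"{path}: duplicate (model, doc_id, run) keys in ensemble")
    return runs


def write_parsed_runs(runs: Sequence[ParsedRun], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in sorted(runs, key=lambda r: r.key):
            fh.write(json.dumps(
                {
                    "model": r.model, "doc_id": r.doc_id, "run": r.run_index,
                    "status": r.status,
                    "relations": [{"source": p.source, "type": p.type, "target": p.target} for p in r.relations],
                    "repair_log": r.repair_log,
                    "warnings": r.warnings,
                },
                ensure_ascii=False) + "\n")


def read_parsed_runs(path: str | Path) -> list[ParsedRun]:
    out: list[ParsedRun] = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(ParsedRun(
                key=(obj["model"], obj["doc_id"], int(obj["run"])),
                relations=[PredictedRelation(d["source"], d["type"], d["target"]) for d in obj["relations"]],
                status=obj["status"],
                repair_log=obj.get("repair_log", []),
                warnings=obj.get("warnings", []),
            ))
    return out
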