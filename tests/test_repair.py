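"""Output repair and parsing: framing, commas, delimiters, validity accounting."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from docre_eval.repair import (
    ParsedRun,
    PredictedRelation,
    RawRunOutput,
    parse_run,
    read_parsed_runs,
    read_raw_runs,
    repair_json,
    tabulate_validity,
    write_parsed_runs,
    write_raw_runs,
)


def run(text: str, model="m", doc="d", idx=0) -> ParsedRun:
    return parse_run(RawRunOutput(model, doc, idx, text))


class TestRepairJson:
    def test_trailing_comma_removed(self):
        text = '{"relations":[{"source":"a","type":"Causes","target":"b"},]}'
        repaired, actions = repair_json(text)
        assert json.loads(repaired)["relations"][0]["source"] == "a"
        assert actions

    def test_valid_json_untouched(self):
        text = '{"entities": [], "relations": []}'
        repaired, actions = repair_json(text)
        assert repaired == text
        assert actions == []

    def test_markdown_fences_stripped(self):
        repaired, actions = repair_json('```json\n{"relations":[]}\n```')
        assert json.loads(repaired) == {"relations": []}
        assert "strip_framing" in actions

    def test_prose_framing_stripped(self):
        repaired, _ = repair_json('Sure! Here is the JSON:\n{"relations": []}\nHope this helps.')
        assert json.loads(repaired) == {"relations": []}

    def test_unclosed_delimiters_closed(self):
        repaired, actions = repair_json('{"relations": [{"source": "a", "type": "Causes", "target": "b"')
        assert json.loads(repaired)["relations"][0]["target"] == "b"
        assert any(a.startswith("close_delimiters") for a in actions)

    def test_comma_inside_string_preserved(self):
        text = '{"relations":[{"source":"a, b","type":"Causes","target":"c"}]}'
        repaired, actions = repair_json(text)
        assert json.loads(repaired)["relations"][0]["source"] == "a, b"

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet='{}[]",: abct\n`', max_size=50))
    def test_idempotent_on_own_output(self, text):
        once, _ = repair_json(text)
        twice, actions = repair_json(once)
        assert twice == once


class TestParseRun:
    def test_wellformed_output_with_entities_section(self):
        payload = {
            "entities": [{"form": "Foc", "type": "Pest"}],
            "relations": [{"source": "Foc", "type": "Causes", "target": "fusariosis"}],
        }
        r = run(json.dumps(payload))
        assert r.status == "valid"
        assert r.relations == [PredictedRelation("Foc", "Causes", "fusariosis")]
        assert r.entity_section == payload["entities"]

    def test_empty_string_unrecoverable(self):
        r = run("")
        assert r.status == "unrecoverable"
        assert r.relations == []

    def test_relation_missing_target_dropped_others_kept(self):
        payload = {"relations": [
            {"source": "a", "type": "Causes", "target": "b"},
            {"source": "c", "type": "Causes"},
        ]}
        r = run(json.dumps(payload))
        assert r.status == "valid"
        assert len(r.relations) == 1
        assert any("target" in w for w in r.warnings)

    def test_missing_relations_key_is_valid_empty(self):
        r = run('{"entities": []}')
        assert r.status == "valid"
        assert r.relations == []

    def test_repaired_status_has_nonempty_log(self):
        r = run('```json\n{"relations": [{"source":"a","type":"t","target":"b"},]}\n```')
        assert r.status == "repaired"
        assert r.repair_log
        assert len(r.relations) == 1

    def test_garbled_premature_termination_unrecoverable(self):
        text = '{"entities": [], "relations": [{"sour' + '"type": "Located in", ' * 6 + '{: "truncated"}'
        r = run(text)
        assert r.status == "unrecoverable"
        assert r.relations == []

    def test_duplicate_triplets_retained_at_parse_time(self):
        payload = {"relations": [{"source": "a", "type": "t", "target": "b"}] * 3}
        r = run(json.dumps(payload))
        assert len(r.relations) == 3

    def test_type_string_kept_verbatim(self):
        r = run('{"relations": [{"source": "a", "type": "located IN", "target": "b"}]}')
        assert r.relations[0].type == "located IN"


class TestTabulateValidity:
    def test_small_ensemble(self):
        runs = [run('{"relations": []}', idx=i) for i in range(4)]
        runs.append(run('```json\n{"relations": []}\n```', idx=4))
        table = tabulate_validity(runs)
        row = table.iloc[0]
        assert row.recoverable == pytest.approx(0.2)
        assert row.unrecoverable == 0.0
        assert row.valid == 1.0

    def test_one_unrecoverable_among_825(self):
        runs = [run('{"relations": []}', idx=i) for i in range(824)]
        runs.append(run("", idx=824))
        row = tabulate_validity(runs).iloc[0]
        assert round(row.unrecoverable, 3) == 0.001
        assert round(row.valid, 3) == 0.999

    def test_all_unrecoverable(self):
        runs = [run("", idx=i) for i in range(10)]
        row = tabulate_validity(runs).iloc[0]
        assert (row.recoverable, row.unrecoverable, row.valid) == (0.0, 1.0, 0.0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            tabulate_validity([])

    def test_per_model_consistency_of_proportions(self):
        runs = [run('{"relations": []}', model="a", idx=i) for i in range(3)]
        runs += [run("", model="b", idx=i) for i in range(2)]
        runs += [run('```json\n{}\n```', model="b", idx=9)]
        table = tabulate_validity(runs).set_index("model")
        for _, row in table.iterrows():
            assert row.valid == pytest.approx(1.0 - row.unrecoverable)
            assert row.recoverable <= row.valid


def test_raw_and_parsed_roundtrip(tmp_path):
    raws = [
        RawRunOutput("m", "d1", 0, '{"relations": [{"source": "a", "type": "t", "target": "b"}]}'),
        RawRunOutput("m", "d1", 1, "garbage"),
    ]
    write_raw_runs(raws, tmp_path / "runs.jsonl")
    assert read_raw_runs(tmp_path / "runs.jsonl") == sorted(raws, key=lambda r: r.run_index)
    parsed = [parse_run(r) for r in raws]
    write_parsed_runs(parsed, tmp_path / "parsed.jsonl")
    back = read_parsed_runs(tmp_path / "parsed.jsonl")
    assert [(p.key, p.status, p.relations) for p in back] == [(p.key, p.status, p.relations) for p in parsed]
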