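"""Pattern-rule engine: match selection, phase execution, cascade behaviour."""

import pytest

from bccnlp.annotations import Document, to_standoff
from bccnlp.gazetteer import Gazetteer, GazetteerEntry, LookupIndex, lookup
from bccnlp.preprocessing import tokenize
from bccnlp.rules import (
    RuleLoadError,
    load_phase_file,
    match_at,
    parse_phase,
    run_cascade,
    run_phase,
)


def _phase(control="appelt", rules=(), inputs=("Token", "Lookup"), name="p"):
    return parse_phase(
        {"phase": {"name": name, "control": control, "input": list(inputs)}, "rules": list(rules)}
    )


def _lookup_rule(name, majors, category="Out", priority=0):
    return {
        "name": name,
        "priority": priority,
        "pattern": [
            {"category": "Lookup", "features": {"majorType": m}, "bind": f"b{i}"}
            for i, m in enumerate(majors)
        ],
        "actions": [
            {
                "create": {
                    "category": category,
                    "span": "match",
                    "features": {"first": {"text": "b0"}},
                }
            }
        ],
    }


def _doc(text, terms):
    doc = Document("d", text)
    tokenize(doc)
    gazetteers = [
        Gazetteer(major, [GazetteerEntry(t, major) for t in ts])
        for major, ts in terms.items()
    ]
    lookup(doc, LookupIndex(gazetteers))
    return doc


def test_appelt_prefers_longest_match():
    doc = _doc(
        "nodular basal cell carcinoma",
        {"subtype": ["nodular"], "diagnosis": ["basal cell carcinoma"]},
    )
    phase = _phase(
        rules=[
            _lookup_rule("short", ["subtype"], category="A"),
            _lookup_rule("long", ["subtype", "diagnosis"], category="B"),
        ]
    )
    m = match_at(phase, doc, 0)
    assert m.rule.name == "long"


def test_appelt_ties_break_by_priority_then_declaration_order():
    doc = _doc("nodular", {"subtype": ["nodular"]})
    low_then_high = _phase(
        rules=[
            _lookup_rule("low", ["subtype"], priority=5),
            _lookup_rule("high", ["subtype"], priority=10),
        ]
    )
    assert match_at(low_then_high, doc, 0).rule.name == "high"
    equal = _phase(
        rules=[
            _lookup_rule("first_declared", ["subtype"], priority=5),
            _lookup_rule("second_declared", ["subtype"], priority=5),
        ]
    )
    assert match_at(equal, doc, 0).rule.name == "first_declared"


def test_run_phase_creates_annotation_with_copied_feature():
    doc = _doc(
        "nodular basal cell carcinoma",
        {"subtype": ["nodular"], "diagnosis": ["basal cell carcinoma"]},
    )
    rule = {
        "name": "diag",
        "pattern": [
            {"category": "Lookup", "features": {"majorType": "subtype"}, "bind": "sub"},
            {"category": "Lookup", "features": {"majorType": "diagnosis"}, "bind": "diag"},
        ],
        "actions": [
            {
                "create": {
                    "category": "MicroscopicDetails",
                    "span": "match",
                    "features": {"subtype": {"text": "sub"}},
                }
            }
        ],
    }
    run_phase(_phase(rules=[rule]), doc)
    created = doc.annset("pipeline").by_category("MicroscopicDetails")
    assert len(created) == 1
    assert (created[0].start, created[0].end) == (0, 28)
    assert created[0].features == {"subtype": "nodular"}


def test_no_match_without_required_element():
    doc = _doc("basal cell carcinoma", {"diagnosis": ["basal cell carcinoma"]})
    rule = _lookup_rule("needs_subtype", ["subtype", "diagnosis"])
    run_phase(_phase(rules=[rule]), doc)
    assert doc.annset("pipeline").by_category("Out") == []


def test_remove_action_deletes_bound_annotation():
    doc = _doc("residual disease", {"prognostic": ["residual disease"]})
    aset = doc.annset("pipeline")
    aset.add("MicroscopicDetails", 0, 16, {"negated": True})
    cleanup = _phase(
        control="all",
        inputs=("MicroscopicDetails",),
        rules=[
            {
                "name": "drop_negated",
                "pattern": [
                    {
                        "category": "MicroscopicDetails",
                        "features": {"negated": True},
                        "bind": "t",
                    }
                ],
                "actions": [{"remove": "t"}],
            }
        ],
    )
    run_phase(cleanup, doc)
    assert aset.by_category("MicroscopicDetails") == []


def test_unbound_label_is_a_load_time_error():
    with pytest.raises(RuleLoadError) as exc:
        _phase(
            rules=[
                {
                    "name": "bad",
                    "pattern": [{"category": "Lookup"}],
                    "actions": [{"remove": "nope"}],
                }
            ]
        )
    assert "unbound" in str(exc.value)


def test_bad_quantifier_is_a_load_time_error():
    with pytest.raises(RuleLoadError):
        _phase(
            rules=[
                {
                    "name": "bad",
                    "pattern": [
                        {"category": "Lookup", "quantifier": {"min": 3, "max": 1}}
                    ],
                    "actions": [{"remove": "x"}],
                }
            ]
        )


def test_duplicate_rule_names_rejected():
    with pytest.raises(RuleLoadError):
        _phase(rules=[_lookup_rule("same", ["a"]), _lookup_rule("same", ["b"])])


def test_empty_cascade_is_identity():
    doc = _doc("nodular", {"subtype": ["nodular"]})
    before = to_standoff(doc, "pipeline")
    run_cascade([], doc)
    assert to_standoff(doc, "pipeline") == before


def test_cascade_is_deterministic(resources):
    from bccnlp.synthesis import GenerationConfig, generate_corpus

    gen1 = generate_corpus(GenerationConfig(n_reports=3, seed=5))
    gen2 = generate_corpus(GenerationConfig(n_reports=3, seed=5))
    for d1, d2 in zip(gen1.corpus, gen2.corpus):
        tokenize(d1), tokenize(d2)
        lookup(d1, resources.index), lookup(d2, resources.index)
        run_cascade(resources.main_phases, d1)
        run_cascade(resources.main_phases, d2)
        assert to_standoff(d1, "pipeline") == to_standoff(d2, "pipeline")


def test_appelt_output_does_not_overlap_within_a_category(small_generated):
    from bccnlp.annotations import overlaps
    from bccnlp.pipeline import INTERMEDIATE_CATEGORIES

    gen, _ = small_generated
    for doc in gen.corpus:
        work = doc.annset("pipeline")
        for cat in INTERMEDIATE_CATEGORIES:
            anns = work.by_category(cat)
            for a, b in zip(anns, anns[1:]):
                assert not overlaps(a.span, b.span)


def test_independent_phases_commute():
    terms = {"subtype": ["nodular"], "prognostic": ["ulceration"]}
    p1 = _phase(rules=[_lookup_rule("r1", ["subtype"], category="A")], name="p1")
    p2 = _phase(rules=[_lookup_rule("r2", ["prognostic"], category="B")], name="p2")
    d1 = _doc("nodular with ulceration", terms)
    d2 = _doc("nodular with ulceration", terms)
    run_cascade([p1, p2], d1)
    run_cascade([p2, p1], d2)
    extract = lambda d: sorted(
        (a.category, a.start, a.end) for a in d.annset("pipeline")
        if a.category in ("A", "B")
    )
    assert extract(d1) == extract(d2)


def test_quantified_elements_are_greedy():
    doc = _doc("a a a b", {"x": ["a"], "y": ["b"]})
    rule = {
        "name": "greedy",
        "pattern": [
            {"category": "Lookup", "features": {"majorType": "x"}, "quantifier": "plus", "bind": "xs"},
            {"category": "Lookup", "features": {"majorType": "y"}, "bind": "b"},
        ],
        "actions": [{"create": {"category": "Out", "span": "match"}}],
    }
    phase = _phase(rules=[rule])
    m = match_at(phase, doc, 0)
    assert (m.start, m.end) == (0, 7)
    assert len(m.bindings["xs"]) == 3


def test_shipped_rule_files_load_with_diagnostics(resources, tmp_path):
    assert any(p.name == "entities" for p in resources.main_phases)
    bad = tmp_path / "bad.yaml"
    bad.write_text(
        "phase: {name: b, control: appelt, input: [Token]}\n"
        "rules:\n- name: r\n  pattern: []\n  actions: []\n"
    )
    with pytest.raises(RuleLoadError) as exc:
        load_phase_file(bad)
    assert "bad.yaml" in str(exc.value)
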