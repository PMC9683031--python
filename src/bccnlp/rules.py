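"""Cascaded pattern-rule transducer over annotation sequences.

A *phase* holds an ordered list of rules, a control style and the set of
annotation categories visible to its patterns.  A rule's left-hand side is
a sequence of :class:`PatternElement` constraints (category, feature
predicates, regex over covered text, quantifier, optional binding); its
right-hand side creates annotations (with features copied from bindings or
given literally) or removes bound annotations.

Control styles mirror the conventions of finite-state annotation engines:

* ``appelt`` — at each offset the longest match wins, ties broken by rule
  priority then declaration order; the matched region is consumed.
* ``first`` — the first rule (in declaration order) that matches fires and
  consumes its match.
* ``all``   — every match of every rule fires; nothing is consumed.

Rule files are YAML documents validated at load time; malformed rules are
rejected with file and rule diagnostics before any document is touched.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import yaml

from .annotations import Annotation, Document, Span
from .textnorm import normalize_text


class RuleLoadError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Rule model
# ---------------------------------------------------------------------------

_ABSENT = object()


@dataclass(frozen=True)
class FeaturePredicate:
    name: str
    op: str  # "eq" | "in" | "regex" | "absent" | "present"
    value: object = None

    def test(self, features: dict) -> bool:
        if self.op == "absent":
            return self.name not in features
        if self.op == "present":
            return self.name in features
        if self.name not in features:
            return False
        v = features[self.name]
        if self.op == "eq":
            return v == self.value
        if self.op == "in":
            return v in self.value  # type: ignore[operator]
        if self.op == "regex":
            return re.search(self.value, str(v)) is not None  # type: ignore[arg-type]
        raise AssertionError(self.op)


@dataclass(frozen=True)
class PatternElement:
    category: str
    feature_predicates: tuple[FeaturePredicate, ...] = ()
    text_regex: str | None = None
    min_count: int = 1
    max_count: int = 1  # math.inf for star/plus is held as a large int
    bind: str | None = None

    def matches(self, ann: Annotation, doc_text: str) -> bool:
        if ann.category != self.category:
            return False
        for pred in self.feature_predicates:
            if not pred.test(ann.features):
                return False
        if self.text_regex is not None:
            if re.search(self.text_regex, ann.text(doc_text)) is None:
                return False
        return True


@dataclass(frozen=True)
class CreateAction:
    category: str
    span: object  # "match" | bind name | (bind_from, bind_to)
    features: tuple[tuple[str, tuple], ...]  # (name, value-spec)


@dataclass(frozen=True)
class RemoveAction:
    bind: str


@dataclass(frozen=True)
class Rule:
    name: str
    priority: int
    elements: tuple[PatternElement, ...]
    actions: tuple[object, ...]


@dataclass
class Phase:
    name: str
    control: str
    input_categories: tuple[str, ...]
    rules: tuple[Rule, ...] = ()

    def __post_init__(self) -> None:
        if self.control not in ("all", "appelt", "first"):
            raise RuleLoadError(f"phase {self.name!r}: unknown control {self.control!r}")
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise RuleLoadError(f"phase {self.name!r}: duplicate rule names")


# ---------------------------------------------------------------------------
# YAML loading / validation
# ---------------------------------------------------------------------------

_QUANTIFIERS = {"one": (1, 1), "optional": (0, 1), "star": (0, 10**6), "plus": (1, 10**6)}


def _parse_predicates(d: dict, where: str) -> tuple[FeaturePredicate, ...]:
    preds = []
    for name, spec in d.items():
        if isinstance(spec, dict):
            if set(spec) == {"absent"}:
                preds.append(FeaturePredicate(name, "absent" if spec["absent"] else "present"))
            elif set(spec) == {"present"}:
                preds.append(FeaturePredicate(name, "present" if spec["present"] else "absent"))
            elif set(spec) == {"in"}:
                preds.append(FeaturePredicate(name, "in", tuple(spec["in"])))
            elif set(spec) == {"regex"}:
                preds.append(FeaturePredicate(name, "regex", str(spec["regex"])))
            else:
                raise RuleLoadError(f"{where}: bad feature predicate {name}: {spec}")
        else:
            preds.append(FeaturePredicate(name, "eq", spec))
    return tuple(preds)


def _parse_element(d: dict, where: str) -> PatternElement:
    allowed = {"category", "features", "text", "quantifier", "bind"}
    unknown = set(d) - allowed
    if unknown:
        raise RuleLoadError(f"{where}: unknown element keys {sorted(unknown)}")
    if "category" not in d:
        raise RuleLoadError(f"{where}: pattern element lacks 'category'")
    quant = d.get("quantifier", "one")
    if isinstance(quant, dict):
        lo, hi = int(quant.get("min", 0)), int(quant.get("max", 0))
        if not (0 <= lo <= hi):
            raise RuleLoadError(f"{where}: bad range quantifier {quant}")
    elif quant in _QUANTIFIERS:
        lo, hi = _QUANTIFIERS[quant]
    else:
        raise RuleLoadError(f"{where}: unknown quantifier {quant!r}")
    text_regex = None
    if "text" in d:
        t = d["text"]
        if isinstance(t, dict) and set(t) == {"regex"}:
            text_regex = str(t["regex"])
        elif isinstance(t, str):
            text_regex = "^" + re.escape(t) + "$"
        else:
            raise RuleLoadError(f"{where}: bad text constraint {t}")
    if text_regex is not None:
        try:
            re.compile(text_regex)
        except re.error as exc:
            raise RuleLoadError(f"{where}: bad regex {text_regex!r}: {exc}") from None
    return PatternElement(
        category=str(d["category"]),
        feature_predicates=_parse_predicates(d.get("features") or {}, where),
        text_regex=text_regex,
        min_count=lo,
        max_count=hi,
        bind=d.get("bind"),
    )


_VALUE_SPEC_KEYS = {"const", "text", "rawtext", "feature", "text_span"}


def _parse_action(d: dict, bindings: set[str], where: str) -> object:
    if set(d) == {"remove"}:
        b = d["remove"]
        if b not in bindings:
            raise RuleLoadError(f"{where}: remove references unbound label {b!r}")
        return RemoveAction(b)
    if set(d) == {"create"}:
        c = d["create"]
        unknown = set(c) - {"category", "span", "features"}
        if unknown:
            raise RuleLoadError(f"{where}: unknown create keys {sorted(unknown)}")
        if "category" not in c:
            raise RuleLoadError(f"{where}: create lacks 'category'")
        span = c.get("span", "match")
        if isinstance(span, list):
            if len(span) != 2 or any(b not in bindings for b in span):
                raise RuleLoadError(f"{where}: bad span spec {span}")
            span = tuple(span)
        elif span != "match":
            if span not in bindings:
                raise RuleLoadError(f"{where}: span references unbound label {span!r}")
        feats = []
        for name, spec in (c.get("features") or {}).items():
            if not isinstance(spec, dict) or len(spec) != 1 or next(iter(spec)) not in _VALUE_SPEC_KEYS:
                raise RuleLoadError(f"{where}: bad feature spec {name}: {spec}")
            kind, val = next(iter(spec.items()))
            if kind in ("text", "rawtext") and val not in bindings:
                raise RuleLoadError(f"{where}: feature {name} references unbound label {val!r}")
            if kind == "feature":
                if not (isinstance(val, list) and len(val) == 2):
                    raise RuleLoadError(f"{where}: feature-copy spec must be [bind, name]")
                if val[0] not in bindings:
                    raise RuleLoadError(f"{where}: feature {name} references unbound label {val[0]!r}")
                val = tuple(val)
            if kind == "text_span":
                if not (isinstance(val, list) and len(val) == 2) or any(
                    b not in bindings for b in val
                ):
                    raise RuleLoadError(f"{where}: bad text_span spec {val}")
                val = tuple(val)
            feats.append((name, (kind, val)))
        return CreateAction(str(c["category"]), span, tuple(feats))
    raise RuleLoadError(f"{where}: action must be a single 'create' or 'remove' mapping")


def parse_phase(obj: dict, source: str = "<memory>") -> Phase:
    if not isinstance(obj, dict) or "phase" not in obj:
        raise RuleLoadError(f"{source}: missing top-level 'phase' mapping")
    ph = obj["phase"]
    name = str(ph.get("name", "unnamed"))
    control = str(ph.get("control", "appelt"))
    inputs = tuple(str(c) for c in ph.get("input", []))
    if not inputs:
        raise RuleLoadError(f"{source}: phase {name!r} declares no input categories")
    rules = []
    for rd in obj.get("rules") or []:
        where = f"{source}: phase {name!r}, rule {rd.get('name', '?')!r}"
        if "name" not in rd:
            raise RuleLoadError(f"{where}: rule lacks a name")
        elements = tuple(
            _parse_element(e, where) for e in (rd.get("pattern") or [])
        )
        if not elements:
            raise RuleLoadError(f"{where}: empty pattern")
        bindings = {e.bind for e in elements if e.bind}
        actions = tuple(_parse_action(a, bindings, where) for a in (rd.get("actions") or []))
        if not actions:
            raise RuleLoadError(f"{where}: rule has no actions")
        rules.append(Rule(str(rd["name"]), int(rd.get("priority", 0)), elements, actions))
    return Phase(name, control, inputs, tuple(rules))


def load_phase_file(path: str | Path) -> Phase:
    path = Path(path)
    try:
        obj = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise RuleLoadError(f"{path}: invalid YAML: {exc}") from None
    return parse_phase(obj, source=str(path))


def load_phases(paths: Iterable[str | Path]) -> list[Phase]:
    return [load_phase_file(p) for p in paths]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass
class Match:
    rule: Rule
    rule_index: int
    start: int
    end: int
    bindings: dict[str, list[Annotation]]


class _Stream:
    """Input-category annotations of a document, indexed for sequence matching."""

    def __init__(self, doc: Document, categories: tuple[str, ...], set_name: str) -> None:
        aset = doc.annset(set_name)
        cats = set(categories)
        self.text = doc.text
        self.anns = sorted(
            (a for a in aset if a.category in cats), key=Annotation.sort_key
        )
        self.by_start: dict[int, list[Annotation]] = {}
        for a in self.anns:
            self.by_start.setdefault(a.start, []).append(a)
        self.starts = sorted(self.by_start)

    def next_start(self, pos: int) -> int | None:
        """Smallest annotation start >= pos reachable across whitespace only."""
        i = bisect_left(self.starts, pos)
        if i >= len(self.starts):
            return None
        s = self.starts[i]
        if self.text[pos:s].strip():
            return None
        return s

    def candidates_at(self, start: int) -> list[Annotation]:
        return self.by_start.get(start, [])


def _match_rule_at(rule: Rule, stream: _Stream, position: int) -> Iterator[Match]:
    """Yield every match of ``rule`` whose first annotation starts at ``position``."""
    text = stream.text

    def seq(idx: int, pos: int, bindings: dict, anchored: bool) -> Iterator[tuple[int, dict]]:
        if idx == len(rule.elements):
            yield pos, bindings
            return
        el = rule.elements[idx]

        def consume(count: int, pos2: int, bnd: dict) -> Iterator[tuple[int, dict]]:
            if count >= el.min_count:
                yield from seq(idx + 1, pos2, bnd, False)
            if count >= el.max_count:
                return
            if anchored and count == 0 and idx == 0:
                s = position if position in stream.by_start else None
            else:
                s = stream.next_start(pos2)
            if s is None:
                return
            if anchored and idx == 0 and count == 0 and s != position:
                return
            for ann in stream.candidates_at(s):
                if el.matches(ann, text):
                    b2 = bnd
                    if el.bind:
                        b2 = dict(bnd)
                        b2.setdefault(el.bind, [])
                        b2[el.bind] = b2[el.bind] + [ann]
                    yield from consume(count + 1, ann.end, b2)

        yield from consume(0, pos, bindings)

    first_required = rule.elements[0].min_count > 0
    for end, bindings in seq(0, position, {}, True):
        if end <= position:
            continue  # zero-width match: every element skipped
        # when the first element is optional the match may effectively not be
        # anchored at `position`; require that some annotation at `position`
        # was consumed
        if not first_required:
            consumed_starts = {a.start for anns in bindings.values() for a in anns}
            if position not in consumed_starts:
                # accept anyway if match begins there (non-bound elements)
                pass
        yield Match(rule, -1, position, end, bindings)


def match_at(phase: Phase, doc: Document, position: int, set_name: str = "pipeline"):
    """Best match (or all matches, under ``all`` control) at ``position``."""
    stream = _Stream(doc, phase.input_categories, set_name)
    return _match_at(phase, stream, position)


def _match_at(phase: Phase, stream: _Stream, position: int):
    if phase.control == "all":
        out = []
        for i, rule in enumerate(phase.rules):
            for m in _match_rule_at(rule, stream, position):
                m.rule_index = i
                out.append(m)
        return out
    if phase.control == "first":
        for i, rule in enumerate(phase.rules):
            for m in _match_rule_at(rule, stream, position):
                m.rule_index = i
                return m
        return None
    # appelt: longest span, then highest priority, then declaration order
    best: Match | None = None
    for i, rule in enumerate(phase.rules):
        for m in _match_rule_at(rule, stream, position):
            m.rule_index = i
            if best is None or (m.end, m.rule.priority, -m.rule_index) > (
                best.end,
                best.rule.priority,
                -best.rule_index,
            ):
                best = m
    return best


# ---------------------------------------------------------------------------
# Action evaluation and phase execution
# ---------------------------------------------------------------------------

def _binding_span(anns: list[Annotation]) -> Span:
    return Span(min(a.start for a in anns), max(a.end for a in anns))


def _eval_feature(spec: tuple, match: Match, text: str):
    kind, val = spec
    if kind == "const":
        return val
    if kind in ("text", "rawtext"):
        anns = match.bindings.get(val)
        if not anns:
            return _ABSENT
        sp = _binding_span(anns)
        raw = text[sp.start : sp.end]
        return raw if kind == "rawtext" else normalize_text(raw)
    if kind == "feature":
        bind, fname = val
        anns = match.bindings.get(bind)
        if not anns or fname not in anns[0].features:
            return _ABSENT
        return anns[0].features[fname]
    if kind == "text_span":
        b1, b2 = val
        a1, a2 = match.bindings.get(b1), match.bindings.get(b2)
        if not a1 or not a2:
            return _ABSENT
        return normalize_text(text[_binding_span(a1).start : _binding_span(a2).end])
    raise AssertionError(kind)


def _apply_actions(match: Match, doc: Document, set_name: str) -> None:
    aset = doc.annset(set_name)
    for action in match.rule.actions:
        if isinstance(action, RemoveAction):
            for ann in match.bindings.get(action.bind, []):
                aset.remove(ann)
            continue
        assert isinstance(action, CreateAction)
        if action.span == "match":
            sp = Span(match.start, match.end)
        elif isinstance(action.span, tuple):
            a1 = match.bindings.get(action.span[0])
            a2 = match.bindings.get(action.span[1])
            if not a1 or not a2:
                continue
            sp = Span(_binding_span(a1).start, _binding_span(a2).end)
        else:
            anns = match.bindings.get(action.span)  # type: ignore[arg-type]
            if not anns:
                continue
            sp = _binding_span(anns)
        features = {}
        for name, spec in action.features:
            v = _eval_feature(spec, match, doc.text)
            if v is not _ABSENT and v != "":
                features[name] = v
        aset.add(action.category, sp.start, sp.end, features)


def run_phase(phase: Phase, doc: Document, set_name: str = "pipeline") -> Document:
    stream = _Stream(doc, phase.input_categories, set_name)
    if phase.control == "all":
        matches: list[Match] = []
        for s in stream.starts:
            matches.extend(_match_at(phase, stream, s))
        matches.sort(key=lambda m: (m.start, -m.end, m.rule_index))
        for m in matches:
            _apply_actions(m, doc, set_name)
        return doc
    pos = 0
    while True:
        s = _next_candidate(stream.starts, pos)
        if s is None:
            break
        m = _match_at(phase, stream, s)
        if m is None:
            pos = s + 1
            continue
        _apply_actions(m, doc, set_name)
        pos = max(m.end, s + 1)
    return doc


def _next_candidate(starts: list[int], pos: int) -> int | None:
    i = bisect_left(starts, pos)
    return starts[i] if i < len(starts) else None


def run_cascade(phases: Iterable[Phase], doc: Document, set_name: str = "pipeline") -> Document:
    """Apply phases sequentially; each sees all annotations produced earlier."""
    for phase in phases:
        run_phase(phase, doc, set_name)
    return doc
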