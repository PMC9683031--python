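"""ConText-style negation / affirmation detection.

Trigger terms open a scope in their direction (forward to the sentence
end, backward to the sentence start, or both), closed early by a
termination term or an optional token-window cap.  Target annotations
wholly inside a negation scope receive ``negated=True``; inside an
affirmation scope, ``affirmed=True``.  Pseudo-triggers (longer phrases
such as "no increase") suppress the trigger they contain.  Negation takes
precedence over affirmation, so the two polarity features are never both
true on one annotation.  Scopes never cross sentence boundaries.

Trigger matching reuses the gazetteer longest-match scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .annotations import Annotation, Document, Span
from .gazetteer import Gazetteer, GazetteerEntry, LookupIndex, read_gazetteer_file

TRIGGER_CATEGORIES = ("negation", "affirmation", "pseudo", "termination")
DIRECTIONS = ("forward", "backward", "bidirectional")


@dataclass(frozen=True)
class TriggerTerm:
    text: str
    category: str  # negation | affirmation | pseudo | termination
    direction: str  # forward | backward | bidirectional

    def __post_init__(self) -> None:
        if self.category not in TRIGGER_CATEGORIES:
            raise ValueError(f"unknown trigger category {self.category!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown trigger direction {self.direction!r}")


def read_triggers(path: str | Path) -> list[TriggerTerm]:
    """Load a trigger lexicon (gazetteer format, majorType=context,
    minorType=category:direction)."""
    gaz = read_gazetteer_file(path)
    triggers = []
    for e in gaz.entries:
        if e.major_type != "context":
            raise ValueError(f"trigger entry {e.term!r} must have majorType 'context'")
        cat, _, direction = e.minor_type.partition(":")
        triggers.append(TriggerTerm(e.term, cat, direction or "forward"))
    return triggers


def compile_triggers(triggers: Iterable[TriggerTerm]) -> LookupIndex:
    entries = [
        GazetteerEntry(t.text, "context", f"{t.category}:{t.direction}")
        for t in triggers
    ]
    return LookupIndex([Gazetteer("context-triggers", entries)])


def apply_context(
    doc: Document,
    targets: Iterable[str],
    triggers: Iterable[TriggerTerm] | LookupIndex,
    set_name: str = "pipeline",
    max_window_tokens: int | None = None,
) -> Document:
    """Set ``negated`` / ``affirmed`` features on target annotations."""
    if isinstance(triggers, LookupIndex):
        index = triggers
    else:
        triggers = list(triggers)
        if not triggers:  # no triggers: identity — every polarity stays unset
            return doc
        index = compile_triggers(triggers)
    aset = doc.annset(set_name)
    sentences = aset.by_category("Sentence")
    if not sentences:
        raise ValueError(f"document '{doc.id}' has no Sentence annotations")
    tokens = [(a.start, a.end) for a in aset.by_category("Token")]
    target_cats = set(targets)
    target_anns = [a for a in aset if a.category in target_cats]

    affirmed: set[int] = set()
    negated: set[int] = set()
    for sent in sentences:
        sent_tokens = [t for t in tokens if sent.start <= t[0] and t[1] <= sent.end]
        if not sent_tokens:
            continue
        hits = index.scan(doc.text, sent_tokens)
        # longest-per-start already; drop starts where the best hit is pseudo
        by_start: dict[int, list] = {}
        for s, e, entry in hits:
            by_start.setdefault(s, []).append((s, e, entry))
        active = []
        terminations = []
        for s in sorted(by_start):
            group = by_start[s]
            cats = {entry.minor_type.split(":")[0] for _, _, entry in group}
            if "pseudo" in cats:
                continue
            for s2, e2, entry in group:
                cat, _, direction = entry.minor_type.partition(":")
                if cat == "termination":
                    terminations.append((s2, e2))
                else:
                    active.append((s2, e2, cat, direction))
        for s, e, cat, direction in active:
            scopes = []
            if direction in ("forward", "bidirectional"):
                end = sent.end
                for ts, _te in terminations:
                    if ts >= e:
                        end = min(end, ts)
                        break
                if max_window_tokens is not None:
                    following = [t for t in sent_tokens if t[0] >= e][:max_window_tokens]
                    if following:
                        end = min(end, following[-1][1])
                    else:
                        end = e
                if e < end:
                    scopes.append(Span(e, end))
            if direction in ("backward", "bidirectional"):
                start = sent.start
                for _ts, te in reversed(terminations):
                    if te <= s:
                        start = max(start, te)
                        break
                if max_window_tokens is not None:
                    preceding = [t for t in sent_tokens if t[1] <= s][-max_window_tokens:]
                    if preceding:
                        start = max(start, preceding[0][0])
                    else:
                        start = s
                if start < s:
                    scopes.append(Span(start, s))
            for scope in scopes:
                for ann in target_anns:
                    if scope.start <= ann.start and ann.end <= scope.end:
                        (negated if cat == "negation" else affirmed).add(ann.id)

    for ann in target_anns:
        if ann.id in negated:
            ann.features["negated"] = True
            ann.features.pop("affirmed", None)
        elif ann.id in affirmed:
            ann.features["affirmed"] = True
    return doc
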