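"""Dictionary (gazetteer) lookup: the first stage of the extraction cascade.

Entries are surface terms tagged with a coarse ``majorType``, an optional
fine ``minorType`` and an optional opaque concept code.  Matching is
case-insensitive unless an entry says otherwise, anchored on token
boundaries, and longest-match-only per start offset; multi-word terms match
across runs of whitespace.

File format (tab-separated, ``#`` comments)::

    term<TAB>majorType<TAB>minorType<TAB>conceptCode

An index file (``index.def``) lists one member lexicon filename per line.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .annotations import Annotation, Document


class GazetteerError(ValueError):
    pass


@dataclass(frozen=True)
class GazetteerEntry:
    term: str
    major_type: str
    minor_type: str = ""
    concept_code: str = ""
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise GazetteerError("gazetteer term must be non-empty")


@dataclass
class Gazetteer:
    name: str
    entries: list[GazetteerEntry] = field(default_factory=list)


def read_gazetteer_file(path: str | Path, name: str | None = None) -> Gazetteer:
    path = Path(path)
    gaz = Gazetteer(name or path.stem)
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise GazetteerError(f"{path}:{lineno}: expected term<TAB>majorType")
        term, major = parts[0], parts[1]
        minor = parts[2] if len(parts) > 2 else ""
        concept = parts[3] if len(parts) > 3 else ""
        flags = parts[4] if len(parts) > 4 else ""
        gaz.entries.append(
            GazetteerEntry(term, major, minor, concept, case_sensitive="cs" in flags)
        )
    return gaz


def read_gazetteer_index(def_path: str | Path) -> list[Gazetteer]:
    def_path = Path(def_path)
    gazetteers = []
    for raw in def_path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        gazetteers.append(read_gazetteer_file(def_path.parent / line))
    return gazetteers


@dataclass(frozen=True)
class _Compiled:
    entry: GazetteerEntry
    regex: re.Pattern
    n_chars: int


class LookupIndex:
    """Longest-match scanner over a collection of gazetteers."""

    def __init__(self, gazetteers: Iterable[Gazetteer]) -> None:
        gazetteers = list(gazetteers)
        entries = [e for g in gazetteers for e in g.entries]
        if not entries:
            raise GazetteerError("cannot compile an empty gazetteer collection")
        seen: dict[tuple[str, str, str], list[GazetteerEntry]] = {}
        for e in entries:
            key = (e.term.lower() if not e.case_sensitive else e.term,
                   e.major_type, e.minor_type)
            seen.setdefault(key, []).append(e)
        dups = {k: v for k, v in seen.items() if len(v) > 1}
        if dups:
            offenders = "; ".join(
                f"{k[0]!r} ({k[1]}/{k[2]}) x{len(v)}" for k, v in sorted(dups.items())
            )
            raise GazetteerError(f"duplicate gazetteer entries: {offenders}")
        # index by folded first word for fast candidate retrieval
        self._by_first: dict[str, list[_Compiled]] = {}
        for e in sorted(entries, key=lambda e: (-len(e.term), e.term, e.major_type, e.minor_type)):
            words = e.term.split()
            pattern = r"\s+".join(re.escape(w) for w in words)
            flags = 0 if e.case_sensitive else re.IGNORECASE
            compiled = _Compiled(e, re.compile(pattern, flags), len(e.term))
            first = _first_alnum_chunk(words[0]).lower()
            self._by_first.setdefault(first, []).append(compiled)

    def scan(
        self,
        text: str,
        token_spans: list[tuple[int, int]],
    ) -> list[tuple[int, int, GazetteerEntry]]:
        """All longest-per-start matches anchored on token boundaries."""
        token_starts = {s for s, _ in token_spans}
        token_ends = {e for _, e in token_spans}
        results: list[tuple[int, int, GazetteerEntry]] = []
        for s, e in token_spans:
            key = text[s:e].lower()
            candidates = self._by_first.get(key)
            if not candidates:
                # multi-character terms whose first word is a sub-chunk (e.g. "o'clock")
                candidates = self._by_first.get(_first_alnum_chunk(text[s:e]).lower())
                if not candidates:
                    continue
            best_end = -1
            best: list[GazetteerEntry] = []
            for c in candidates:
                m = c.regex.match(text, s)
                if m is None or m.end() not in token_ends:
                    continue
                # token-boundary anchoring at the start
                if s not in token_starts:
                    continue
                if m.end() > best_end:
                    best_end, best = m.end(), [c.entry]
                elif m.end() == best_end:
                    best.append(c.entry)
            for entry in sorted(best, key=lambda e: (e.major_type, e.minor_type, e.term)):
                results.append((s, best_end, entry))
        results.sort(key=lambda r: (r[0], -r[1]))
        return results


def _first_alnum_chunk(word: str) -> str:
    m = re.match(r"[A-Za-z0-9]+", word)
    return m.group() if m else word


def compile_gazetteers(gazetteers: Iterable[Gazetteer]) -> LookupIndex:
    return LookupIndex(gazetteers)


def lookup(doc: Document, index: LookupIndex, set_name: str = "pipeline") -> list[Annotation]:
    """Emit ``Lookup`` annotations over the document's Token layer."""
    aset = doc.annset(set_name)
    tokens = [(a.start, a.end) for a in aset.by_category("Token")]
    if not tokens:
        raise ValueError(f"document '{doc.id}' has no Token annotations in set '{set_name}'")
    out = []
    for start, end, entry in index.scan(doc.text, tokens):
        features = {"majorType": entry.major_type}
        if entry.minor_type:
            features["minorType"] = entry.minor_type
        if entry.concept_code:
            features["conceptCode"] = entry.concept_code
        out.append(aset.add("Lookup", start, end, features))
    return out
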