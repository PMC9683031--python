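"""Document / annotation data model.

Standoff annotations are typed character spans with a flat feature map,
stored separately from the immutable report text.  Offsets are 0-based,
half-open ``[start, end)``.  A :class:`Document` owns one or more named
:class:`AnnotationSet` objects ("pipeline", "system", "gold",
"annotatorA", ...); a :class:`Corpus` is an ordered collection of
documents with unique identifiers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

Scalar = str | int | float | bool


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Span:
    """Half-open character interval ``[start, end)``; empty spans are forbidden."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Span") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def overlaps(a: Span, b: Span) -> bool:
    """True iff the two spans share at least one character."""
    return a.start < b.end and b.start < a.end


def coextensive(a: Span, b: Span) -> bool:
    """True iff the two spans have identical extents."""
    return a.start == b.start and a.end == b.end


@dataclass
class Annotation:
    """A typed span with a flat feature map (scalar values only)."""

    id: int
    category: str
    span: Span
    features: dict[str, Scalar] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.category:
            raise AnnotationError("annotation category must be non-empty")

    @property
    def start(self) -> int:
        return self.span.start

    @property
    def end(self) -> int:
        return self.span.end

    def text(self, document_text: str) -> str:
        return document_text[self.span.start : self.span.end]

    def sort_key(self) -> tuple[int, int, int]:
        # start ascending, end descending (longer first), id as final tie-break
        return (self.span.start, -self.span.end, self.id)


class AnnotationSet:
    """A named collection of annotations with unique ids, kept in span order."""

    def __init__(self, name: str, doc: "Document | None" = None) -> None:
        self.name = name
        self._doc = doc
        self._by_id: dict[int, Annotation] = {}
        self._next_id = 0

    @property
    def doc_id(self) -> str | None:
        return self._doc.id if self._doc is not None else None

    def add(
        self,
        category: str,
        start: int,
        end: int,
        features: Mapping[str, Scalar] | None = None,
        id: int | None = None,
    ) -> Annotation:
        span = Span(start, end)
        if self._doc is not None and end > len(self._doc.text):
            raise AnnotationError(
                f"span [{start}, {end}) exceeds document '{self._doc.id}' "
                f"length {len(self._doc.text)}"
            )
        if id is None:
            id = self._next_id
        elif id in self._by_id:
            raise AnnotationError(f"duplicate annotation id {id} in set '{self.name}'")
        ann = Annotation(id, category, span, dict(features or {}))
        self._by_id[id] = ann
        self._next_id = max(self._next_id, id + 1)
        return ann

    def remove(self, ann: Annotation | int) -> None:
        key = ann.id if isinstance(ann, Annotation) else ann
        self._by_id.pop(key, None)

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Annotation]:
        return iter(sorted(self._by_id.values(), key=Annotation.sort_key))

    def by_category(self, category: str) -> list[Annotation]:
        return [a for a in self if a.category == category]

    def categories(self) -> list[str]:
        return sorted({a.category for a in self._by_id.values()})

    def select(self, category: str, window: Span | None = None) -> list[Annotation]:
        """Annotations of ``category`` overlapping ``window``, in span order."""
        out = []
        for a in self:
            if a.category != category:
                continue
            if window is None or overlaps(a.span, window):
                out.append(a)
        return out


class Document:
    """One histopathology report: immutable text plus named annotation sets."""

    def __init__(self, id: str, text: str) -> None:
        self.id = id
        self._text = text
        self.sets: dict[str, AnnotationSet] = {}

    @property
    def text(self) -> str:
        return self._text

    def annset(self, name: str, create: bool = True) -> AnnotationSet:
        if name not in self.sets:
            if not create:
                raise KeyError(f"document '{self.id}' has no annotation set '{name}'")
            self.sets[name] = AnnotationSet(name, doc=self)
        return self.sets[name]

    def select(self, set_name: str, category: str, window: Span | None = None):
        return self.annset(set_name, create=False).select(category, window)


class Corpus:
    """Ordered collection of documents with unique ids."""

    def __init__(self, documents: Iterable[Document] = ()) -> None:
        self.documents: list[Document] = []
        self._by_id: dict[str, Document] = {}
        for d in documents:
            self.add(d)

    def add(self, doc: Document) -> None:
        if doc.id in self._by_id:
            raise AnnotationError(f"duplicate document id '{doc.id}'")
        self.documents.append(doc)
        self._by_id[doc.id] = doc

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, doc_id: str) -> Document:
        return self._by_id[doc_id]


# ---------------------------------------------------------------------------
# Standoff JSON I/O
# ---------------------------------------------------------------------------

def to_standoff(doc: Document, set_name: str) -> dict:
    aset = doc.annset(set_name, create=False)
    return {
        "doc_id": doc.id,
        "set": set_name,
        "annotations": [
            {
                "id": a.id,
                "category": a.category,
                "start": a.span.start,
                "end": a.span.end,
                "features": a.features,
            }
            for a in aset
        ],
    }


def write_standoff(doc: Document, set_name: str, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(to_standoff(doc, set_name), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_standoff(path_or_obj, doc: Document) -> AnnotationSet:
    """Load a standoff JSON file (or parsed dict) into ``doc``.

    A missing ``features`` key on an annotation is tolerated and treated as
    an empty map.
    """
    if isinstance(path_or_obj, (str, Path)):
        obj = json.loads(Path(path_or_obj).read_text(encoding="utf-8"))
    else:
        obj = path_or_obj
    if obj.get("doc_id") != doc.id:
        raise AnnotationError(
            f"standoff doc_id {obj.get('doc_id')!r} does not match document {doc.id!r}"
        )
    aset = doc.annset(obj["set"])
    for rec in obj["annotations"]:
        aset.add(
            rec["category"],
            rec["start"],
            rec["end"],
            rec.get("features") or {},
            id=rec["id"],
        )
    return aset


def to_brat(doc: Document, set_name: str) -> str:
    """Render a set as BRAT ``.ann`` lines (T spans, A attributes) for inspection."""
    lines = []
    aset = doc.annset(set_name, create=False)
    attr_n = 0
    for i, a in enumerate(aset, start=1):
        surface = a.text(doc.text).replace("\n", " ")
        lines.append(f"T{i}\t{a.category} {a.span.start} {a.span.end}\t{surface}")
        for k, v in sorted(a.features.items()):
            if isinstance(v, bool) and v:
                attr_n += 1
                lines.append(f"A{attr_n}\t{k} T{i}")
    return "\n".join(lines) + ("\n" if lines else "")
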