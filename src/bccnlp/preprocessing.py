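"""Deterministic tokenisation, sentence splitting and report-section segmentation.

Two token policies are provided:

* ``general`` — drives the extraction pipeline: maximal alphanumeric runs
  (decimal numbers kept whole) plus single punctuation characters, each
  token carrying a ``kind`` feature (``word`` / ``number`` / ``punct``).
* ``capture`` — the corpus-sizing token definition: a token is a maximal
  alphanumeric sequence that begins with a letter; runs beginning with a
  digit and all punctuation are not tokens.

Sections follow the canonical structure of a UK skin-cancer histopathology
report: accession number, excision date, clinical details, macroscopic
details, microscopic details, microscopic measurements, report details,
requestor and supplementary report.  Headers are recognised from a
configurable, case-insensitive synonym list at line start; text before the
first header is labelled ``ReportDetails``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .annotations import Annotation, Document, Span

SECTION_LABELS = (
    "AccessionNumber",
    "ExcisionDate",
    "ClinicalDetails",
    "MacroscopicDetails",
    "MicroscopicDetails",
    "MicroscopicMeasurements",
    "ReportDetails",
    "Requestor",
    "SupplementaryReport",
)

DEFAULT_SECTION_HEADERS: dict[str, list[str]] = {
    "AccessionNumber": ["accession number", "accession no", "lab number", "lab no"],
    "ExcisionDate": ["excision date", "date of excision"],
    "ClinicalDetails": ["clinical details", "clinical history", "clinical information"],
    "MacroscopicDetails": [
        "macroscopic details",
        "macroscopic description",
        "macroscopy",
    ],
    "MicroscopicDetails": [
        "microscopic details",
        "microscopic description",
        "microscopy",
        "histology",
    ],
    "MicroscopicMeasurements": ["microscopic measurements", "tumour measurements"],
    "ReportDetails": ["report details"],
    "Requestor": ["requestor", "requested by", "referring clinician"],
    "SupplementaryReport": ["supplementary report", "supplementary"],
}

_GENERAL_RE = re.compile(r"\d+\.\d+|[A-Za-z0-9]+|\S")
_ALNUM_RUN_RE = re.compile(r"[A-Za-z0-9]+")

# abbreviations that never end a sentence / only end one before an upper-case start
_HARD_ABBREV = {"dr", "mr", "mrs", "ms", "prof", "st", "vs", "approx", "fig"}
_SOFT_ABBREV = {"mm", "cm"}


@dataclass(frozen=True)
class TokenPolicy:
    name: str  # "general" | "capture"

    def __post_init__(self) -> None:
        if self.name not in ("general", "capture"):
            raise ValueError(f"unknown token policy {self.name!r}")


def _token_kind(text: str) -> str:
    if any(c.isalpha() for c in text):
        return "word"
    if any(c.isdigit() for c in text):
        return "number"
    return "punct"


def tokenize_text(text: str, policy: str = "general") -> list[tuple[int, int, str]]:
    """Return ``(start, end, kind)`` triples for every token in ``text``."""
    TokenPolicy(policy)
    out: list[tuple[int, int, str]] = []
    if policy == "general":
        for m in _GENERAL_RE.finditer(text):
            out.append((m.start(), m.end(), _token_kind(m.group())))
    else:  # capture: alphanumeric run beginning with a letter
        for m in _ALNUM_RUN_RE.finditer(text):
            if m.group()[0].isalpha():
                out.append((m.start(), m.end(), "word"))
    return out


def capture_tokens(text: str) -> list[str]:
    """Lower-cased capture-policy token strings of ``text``."""
    return [text[s:e].lower() for s, e, _ in tokenize_text(text, "capture")]


def tokenize(doc: Document, policy: str = "general", set_name: str = "pipeline") -> list[Annotation]:
    aset = doc.annset(set_name)
    anns = []
    for start, end, kind in tokenize_text(doc.text, policy):
        anns.append(aset.add("Token", start, end, {"kind": kind}))
    return anns


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

def _word_before(text: str, idx: int) -> str:
    j = idx
    while j > 0 and (text[j - 1].isalnum() or text[j - 1] == "'"):
        j -= 1
    return text[j:idx].lower()


def split_sentence_spans(text: str) -> list[Span]:
    if not text:
        raise ValueError("cannot sentence-split empty text")
    spans: list[Span] = []
    for line_m in re.finditer(r"[^\n]+", text):
        line, off = line_m.group(), line_m.start()
        start = 0
        i = 0
        while i < len(line):
            c = line[i]
            if c in ".?!" and (i + 1 == len(line) or line[i + 1].isspace()):
                prev = _word_before(line, i)
                boundary = True
                if c == ".":
                    if prev in _HARD_ABBREV:
                        boundary = False
                    elif prev in _SOFT_ABBREV:
                        # unit abbreviation: split only before a clearly new sentence
                        rest = line[i + 1 :].lstrip()
                        boundary = bool(rest) and (rest[0].isupper() or rest[0].isdigit())
                    elif i >= 1 and line[i - 1].isdigit() and i + 1 < len(line) and line[i + 1].isdigit():
                        boundary = False  # decimal guard (defensive; needs no space after)
                if boundary:
                    seg = line[start : i + 1]
                    if seg.strip():
                        s = start + len(seg) - len(seg.lstrip())
                        spans.append(Span(off + s, off + i + 1))
                    start = i + 1
            i += 1
        tail = line[start:]
        if tail.strip():
            s = start + len(tail) - len(tail.lstrip())
            e = start + len(tail.rstrip())
            spans.append(Span(off + s, off + e))
    return spans


def split_sentences(doc: Document, set_name: str = "pipeline") -> list[Annotation]:
    aset = doc.annset(set_name)
    return [aset.add("Sentence", sp.start, sp.end) for sp in split_sentence_spans(doc.text)]


# ---------------------------------------------------------------------------
# Section segmentation
# ---------------------------------------------------------------------------

def _compile_headers(headers: dict[str, list[str]]) -> list[tuple[str, str]]:
    pairs = []
    for label, synonyms in headers.items():
        if label not in SECTION_LABELS:
            raise ValueError(f"unknown section label {label!r}")
        for syn in synonyms:
            pairs.append((syn.lower(), label))
    # longest synonym first so e.g. "supplementary report" beats "supplementary"
    pairs.sort(key=lambda p: (-len(p[0]), p[0]))
    return pairs


def segment_section_spans(
    text: str, headers: dict[str, list[str]] | None = None
) -> list[tuple[str, Span]]:
    """Split ``text`` into labelled section spans.

    A recognised header at line start opens a section that runs to the next
    header (or end of text); preamble before the first header — or the whole
    report when no header matches — is labelled ``ReportDetails``.
    """
    pairs = _compile_headers(headers or DEFAULT_SECTION_HEADERS)
    marks: list[tuple[int, str]] = []
    for line_m in re.finditer(r"[^\n]+", text):
        line = line_m.group()
        stripped = line.lstrip()
        indent = len(line) - len(stripped)
        low = stripped.lower()
        for syn, label in pairs:
            if low.startswith(syn):
                rest = low[len(syn) :]
                if rest == "" or rest[0] in ":. \t":
                    marks.append((line_m.start() + indent, label))
                    break
    sections: list[tuple[str, Span]] = []
    if not marks:
        if text.strip():
            sections.append(("ReportDetails", _trimmed(text, 0, len(text))))
        return sections
    if text[: marks[0][0]].strip():
        sections.append(("ReportDetails", _trimmed(text, 0, marks[0][0])))
    for i, (start, label) in enumerate(marks):
        end = marks[i + 1][0] if i + 1 < len(marks) else len(text)
        sections.append((label, _trimmed(text, start, end)))
    return sections


def _trimmed(text: str, start: int, end: int) -> Span:
    seg = text[start:end]
    s = start + len(seg) - len(seg.lstrip())
    e = start + len(seg.rstrip())
    return Span(s, max(e, s + 1))


def segment_sections(
    doc: Document,
    headers: dict[str, list[str]] | None = None,
    set_name: str = "pipeline",
) -> list[Annotation]:
    aset = doc.annset(set_name)
    return [
        aset.add(label, sp.start, sp.end)
        for label, sp in segment_section_spans(doc.text, headers)
    ]
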