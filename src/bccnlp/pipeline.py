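"""End-to-end BCC extraction: schema, measurement parsing, cascade assembly,
specimen/lesion record building and CSV output.

The pipeline runs tokenise -> sentence split -> section segmentation ->
gazetteer lookup -> main rule cascade -> polarity (negation/affirmation)
detection -> cleanup cascade -> record assembly.  Cascade rules emit
intermediate categories (Diagnosis, PrognosticFactor, Measurement, ...);
each surviving intermediate is then re-labelled with its enclosing
section's label, so the final entity inventory is the nine canonical
report categories.  Records are grouped per specimen and lesion and
written as RFC-4180 CSV, one row per (report, specimen, lesion).
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .annotations import Annotation, Corpus, Document, Span
from .context import TriggerTerm, apply_context, compile_triggers, read_triggers
from .gazetteer import LookupIndex, lookup, read_gazetteer_index
from .preprocessing import (
    DEFAULT_SECTION_HEADERS,
    SECTION_LABELS,
    segment_sections,
    split_sentences,
    tokenize,
)
from .rules import Phase, load_phase_file, run_cascade

logger = logging.getLogger(__name__)

#: categories produced by the cascade, re-labelled by section at assembly time
INTERMEDIATE_CATEGORIES = (
    "AccessionValue",
    "DateOfExcision",
    "LesionDescription",
    "Diagnosis",
    "PrognosticFactor",
    "ExcisionStatus",
    "SpecimenDescription",
    "Measurement",
    "ReportAuthorisation",
    "RequestorDetail",
)


class ResourceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Extraction schema
# ---------------------------------------------------------------------------

FEATURE_KINDS = ("text", "number", "unit_value", "date", "boolean", "clock")


@dataclass
class ExtractionSchema:
    """The closed feature inventory of the nine entity categories."""

    categories: dict[str, dict[str, str]]  # category -> {feature: kind}

    def __post_init__(self) -> None:
        for cat, feats in self.categories.items():
            if cat not in SECTION_LABELS:
                raise ResourceError(f"schema category {cat!r} is not a canonical entity")
            for name, kind in feats.items():
                if kind not in FEATURE_KINDS:
                    raise ResourceError(f"schema {cat}.{name}: unknown kind {kind!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExtractionSchema":
        obj = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(categories={c: dict(f or {}) for c, f in obj["categories"].items()})

    def validate_annotation(self, ann: Annotation) -> None:
        feats = self.categories.get(ann.category)
        if feats is None:
            raise ResourceError(f"annotation category {ann.category!r} not in schema")
        unknown = set(ann.features) - set(feats)
        if unknown:
            raise ResourceError(
                f"{ann.category} annotation carries unknown features {sorted(unknown)}"
            )


# ---------------------------------------------------------------------------
# Measurement parsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Measurement:
    """A linear measurement normalised to millimetres."""

    value: float  # always mm
    unit: str = "mm"
    qualifier: str | None = None  # exact | less_than | greater_than | at_least
    clock: int | None = None  # 1..12
    axis: str | None = None  # peripheral | deep | thickness | diameter | dim1..dim3

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("measurement value must be >= 0")
        if self.clock is not None and not (1 <= self.clock <= 12):
            raise ValueError("clock position must be in 1..12")


_NUM = r"\d+(?:\.\d+)?"
_TRIPLE_RE = re.compile(
    rf"({_NUM})\s*[xX×]\s*({_NUM})\s*[xX×]\s*({_NUM})\s*(mm|cm)\b", re.IGNORECASE
)
_SINGLE_RE = re.compile(
    rf"(?:(less\s+than|greater\s+than|more\s+than|at\s+least|<|>)\s*)?({_NUM})\s*(mm|cm)\b",
    re.IGNORECASE,
)
_CLOCK_RE = re.compile(rf"at\s*(\d{{1,2}})\s*o\W?\s*clock", re.IGNORECASE)
_AXIS_PHRASES = {
    "peripheral clearance": "peripheral",
    "peripheral margin": "peripheral",
    "deep clearance": "deep",
    "deep margin": "deep",
    "tumour thickness": "thickness",
    "thickness": "thickness",
    "tumour diameter": "diameter",
    "diameter": "diameter",
}
_QUALIFIERS = {
    "less than": "less_than",
    "<": "less_than",
    "greater than": "greater_than",
    "more than": "greater_than",
    ">": "greater_than",
    "at least": "at_least",
}


def _to_mm(value: float, unit: str) -> float:
    return value * 10.0 if unit.lower() == "cm" else value


def parse_measurement(text: str, axis_hint: str | None = None) -> list[Measurement]:
    """Parse the measurements in a phrase; unparseable input yields ``[]``.

    Recognises ``<num> mm|cm``, dimension triples ``a x b x c mm`` (the unit
    distributes over all three), qualifiers (``less than``, ``<``, ...) and
    clock positions (``at 12 o'clock``).  Centimetre values are converted
    to millimetres.
    """
    if not text.strip():
        raise ValueError("cannot parse an empty phrase")
    axis = axis_hint
    low = text.lower()
    if axis is None:
        for phrase, ax in _AXIS_PHRASES.items():
            if phrase in low:
                axis = ax
                break
    m3 = _TRIPLE_RE.search(text)
    if m3:
        unit = m3.group(4)
        return [
            Measurement(_to_mm(float(m3.group(i + 1)), unit), "mm", axis=f"dim{i + 1}")
            for i in range(3)
        ]
    m1 = _SINGLE_RE.search(text)
    if m1 is None:
        logger.info("no measurement parsed from %r", text)
        return []
    qualifier = None
    if m1.group(1):
        qualifier = _QUALIFIERS.get(" ".join(m1.group(1).lower().split()))
    clock = None
    mc = _CLOCK_RE.search(text)
    if mc:
        c = int(mc.group(1))
        if 1 <= c <= 12:
            clock = c
    return [
        Measurement(
            _to_mm(float(m1.group(2)), m1.group(3)),
            "mm",
            qualifier=qualifier,
            clock=clock,
            axis=axis,
        )
    ]


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------

DEFAULT_RESOURCE_DIR = Path(__file__).parent / "resources"


@dataclass
class Resources:
    index: LookupIndex
    main_phases: list[Phase]
    cleanup_phases: list[Phase]
    triggers: list[TriggerTerm]
    trigger_index: LookupIndex
    schema: ExtractionSchema
    section_headers: dict[str, list[str]]
    tokenizer_policy: str = "general"
    context_targets: tuple[str, ...] = ("PrognosticFactor",)
    max_window_tokens: int | None = None
    checksums: dict[str, str] = field(default_factory=dict)


def load_resources(directory: str | Path | None = None) -> Resources:
    """Load and validate gazetteers, rules, triggers, schema and config."""
    directory = Path(directory) if directory else DEFAULT_RESOURCE_DIR
    config_path = directory / "config.yaml"
    if not config_path.exists():
        raise ResourceError(f"missing config file {config_path}")
    cfg = yaml.safe_load(config_path.read_text(encoding="utf-8")) or {}

    gaz_index_path = directory / cfg.get("gazetteers", "gazetteers/index.def")
    gazetteers = read_gazetteer_index(gaz_index_path)
    index = LookupIndex(gazetteers)

    main_phases = [load_phase_file(directory / p) for p in cfg.get("rules", [])]
    cleanup_phases = [load_phase_file(directory / p) for p in cfg.get("cleanup_rules", [])]
    triggers = read_triggers(directory / cfg.get("triggers", "triggers.lst"))
    schema = ExtractionSchema.from_yaml(directory / cfg.get("schema", "schema.yaml"))

    headers = cfg.get("sections", {}).get("headers") or DEFAULT_SECTION_HEADERS
    policy = cfg.get("tokenizer", {}).get("policy", "general")
    targets = tuple(cfg.get("context", {}).get("targets", ["PrognosticFactor"]))
    window = cfg.get("context", {}).get("max_window_tokens")

    checksums = {}
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.suffix in (".lst", ".def", ".yaml"):
            checksums[str(p.relative_to(directory))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()

    return Resources(
        index=index,
        main_phases=main_phases,
        cleanup_phases=cleanup_phases,
        triggers=triggers,
        trigger_index=compile_triggers(triggers),
        schema=schema,
        section_headers=headers,
        tokenizer_policy=policy,
        context_targets=targets,
        max_window_tokens=window,
        checksums=checksums,
    )


def validate_resources(directory: str | Path | None = None) -> list[str]:
    """Return a list of problems (empty when the resource set is valid)."""
    try:
        load_resources(directory)
    except Exception as exc:  # noqa: BLE001 - surface every validation failure
        return [str(exc)]
    return []


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

RECORD_COLUMNS = (
    "accession_number",
    "excision_date",
    "requestor_name",
    "requestor_department",
    "site",
    "laterality",
    "lesion_type",
    "clinical_query",
    "specimen_type",
    "specimen_dim1_mm",
    "specimen_dim2_mm",
    "specimen_dim3_mm",
    "subtype",
    "tag",
    "perineural_invasion",
    "lymphovascular_invasion",
    "ulceration",
    "residual_disease",
    "tumour_confined",
    "completeness_of_excision",
    "tumour_thickness_mm",
    "tumour_diameter_mm",
    "peripheral_clearance_mm",
    "peripheral_clearance_clock",
    "deep_clearance_mm",
    "supplementary_finding",
    "report_author",
    "report_date",
)

_FACTOR_COLUMNS = {
    "perineural_invasion": "perineural_invasion",
    "lymphovascular_invasion": "lymphovascular_invasion",
    "ulceration": "ulceration",
    "residual_disease": "residual_disease",
    "tumour": "tumour_confined",
}

_AXIS_COLUMNS = {
    "thickness": "tumour_thickness_mm",
    "diameter": "tumour_diameter_mm",
    "peripheral": "peripheral_clearance_mm",
    "deep": "deep_clearance_mm",
}


@dataclass
class SpecimenRecord:
    """Structured output for one lesion of one specimen of one report."""

    report_id: str
    specimen: str
    lesion_index: int
    values: dict[str, object] = field(default_factory=dict)

    def key(self) -> tuple[str, str, int]:
        return (self.report_id, self.specimen, self.lesion_index)

    def as_row(self) -> list:
        return [self.report_id, self.specimen, self.lesion_index] + [
            self.values.get(c, "") for c in RECORD_COLUMNS
        ]


def _polarity(features: dict) -> str:
    if features.get("negated"):
        return "negated"
    if features.get("affirmed"):
        return "affirmed"
    return "mentioned"


_SPECIMEN_LABEL_RE = re.compile(r"(?m)(?:^|(?<=:)\s)([A-Z]|\d{1,2})\.(?=\s)")


def _specimen_map(text: str, section: Annotation) -> list[tuple[int, str]]:
    """(offset, label) pairs for specimen labels inside a section."""
    seg = text[section.start : section.end]
    return [
        (section.start + m.start(1), m.group(1))
        for m in _SPECIMEN_LABEL_RE.finditer(seg)
    ]


def _label_for(offset: int, labels: list[tuple[int, str]]) -> str:
    current = "1"
    for pos, lab in labels:
        if pos <= offset:
            current = lab
        else:
            break
    return current


def _iso_date(features: dict) -> str:
    try:
        d, m, y = int(features["day"]), int(features["month"]), int(features["year"])
        return f"{y:04d}-{m:02d}-{d:02d}"
    except (KeyError, ValueError):
        return ""


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract(doc: Document, resources: Resources) -> list[SpecimenRecord]:
    """Run the full pipeline on one document.

    Annotates the document's ``pipeline`` working set and ``system`` output
    set, and returns the per-lesion records.
    """
    if not doc.text.strip():
        raise ValueError(f"document '{doc.id}' has empty text")
    work = "pipeline"
    tokenize(doc, resources.tokenizer_policy, work)
    split_sentences(doc, work)
    sections = segment_sections(doc, resources.section_headers, work)
    lookup(doc, resources.index, work)
    run_cascade(resources.main_phases, doc, work)
    apply_context(
        doc,
        resources.context_targets,
        resources.trigger_index,
        work,
        resources.max_window_tokens,
    )
    run_cascade(resources.cleanup_phases, doc, work)

    # re-label intermediates with the enclosing section's label
    system = doc.annset("system")
    intermediates = [
        a for a in doc.annset(work) if a.category in INTERMEDIATE_CATEGORIES
    ]
    sec_list = [(s.start, s.end, s.category) for s in sections]
    final: list[Annotation] = []
    for ann in intermediates:
        label = "ReportDetails"
        for s, e, cat in sec_list:
            if s <= ann.start and ann.start < e:
                label = cat
        out = system.add(label, ann.start, ann.end, dict(ann.features))
        resources.schema.validate_annotation(out)
        final.append(out)

    return _assemble_records(doc, sections, final)


def _assemble_records(
    doc: Document, sections: list[Annotation], final: list[Annotation]
) -> list[SpecimenRecord]:
    text = doc.text
    by_section_cat: dict[str, list[Annotation]] = {}
    for a in final:
        by_section_cat.setdefault(a.category, []).append(a)

    doc_values: dict[str, object] = {}
    for a in by_section_cat.get("AccessionNumber", []):
        doc_values["accession_number"] = a.features.get("value", "")
    for a in by_section_cat.get("ExcisionDate", []):
        doc_values["excision_date"] = _iso_date(a.features)
    for a in by_section_cat.get("Requestor", []):
        doc_values["requestor_name"] = a.features.get("name", "")
        doc_values["requestor_department"] = a.features.get("department", "")
    for a in by_section_cat.get("ReportDetails", []):
        if "author" in a.features:
            doc_values["report_author"] = a.features["author"]
            doc_values["report_date"] = _iso_date(a.features)
    for a in by_section_cat.get("ClinicalDetails", []):
        if "site" in a.features:
            doc_values["site"] = a.features["site"]
            doc_values["lesion_type"] = a.features.get("lesion_type", "")
            if "laterality" in a.features:
                doc_values["laterality"] = a.features["laterality"]
        elif "tag" in a.features:
            doc_values["clinical_query"] = a.features["tag"]
    for a in by_section_cat.get("SupplementaryReport", []):
        if "tag" in a.features:
            doc_values["supplementary_finding"] = a.features["tag"]

    # specimen contexts per sectioned region
    labels_by_cat: dict[str, list[tuple[int, str]]] = {}
    for s in sections:
        if s.category in (
            "MacroscopicDetails",
            "MicroscopicDetails",
            "MicroscopicMeasurements",
        ):
            labels_by_cat.setdefault(s.category, []).extend(_specimen_map(text, s))

    def spec_label(a: Annotation) -> str:
        return _label_for(a.start, labels_by_cat.get(a.category, []))

    # lesions: one per Diagnosis-bearing annotation in the microscopic section
    lesions: dict[str, list[dict[str, object]]] = {}
    for a in by_section_cat.get("MicroscopicDetails", []):
        if "tag" in a.features:
            lab = spec_label(a)
            lesion = {"tag": a.features["tag"]}
            if "subtype" in a.features:
                lesion["subtype"] = a.features["subtype"]
            lesions.setdefault(lab, []).append(lesion)

    for a in by_section_cat.get("MicroscopicDetails", []):
        lab = spec_label(a)
        targets = lesions.get(lab) or lesions.setdefault(lab, [{}])
        lesion = targets[-1]
        if "factor" in a.features:
            col = _FACTOR_COLUMNS.get(str(a.features["factor"]))
            if col:
                lesion[col] = _polarity(a.features)
        if "completeness_of_excision" in a.features:
            lesion["completeness_of_excision"] = a.features["completeness_of_excision"]

    for a in by_section_cat.get("MicroscopicMeasurements", []):
        lab = _label_for(a.start, labels_by_cat.get("MicroscopicMeasurements", []))
        targets = lesions.get(lab) or lesions.setdefault(lab, [{}])
        lesion = targets[-1]
        parsed = parse_measurement(a.text(text), axis_hint=a.features.get("axis"))
        for meas in parsed:
            col = _AXIS_COLUMNS.get(meas.axis or "")
            if col:
                lesion[col] = meas.value
                if meas.axis == "peripheral" and meas.clock is not None:
                    lesion["peripheral_clearance_clock"] = meas.clock

    macro: dict[str, dict[str, object]] = {}
    for a in by_section_cat.get("MacroscopicDetails", []):
        lab = _label_for(a.start, labels_by_cat.get("MacroscopicDetails", []))
        entry = macro.setdefault(lab, {})
        if "specimen_type" in a.features:
            entry["specimen_type"] = a.features["specimen_type"]
        dims = parse_measurement(a.text(text))
        for meas in dims:
            if meas.axis in ("dim1", "dim2", "dim3"):
                entry[f"specimen_{meas.axis}_mm"] = meas.value

    records = []
    for lab in sorted(lesions, key=_specimen_sort_key):
        for i, lesion in enumerate(lesions[lab]):
            values = dict(doc_values)
            values.update(macro.get(lab, {}))
            values.update(lesion)
            records.append(SpecimenRecord(doc.id, lab, i, values))
    return records


def _specimen_sort_key(label: str):
    return (0, int(label)) if label.isdigit() else (1, label)


def extract_corpus(corpus: Corpus, resources: Resources) -> list[SpecimenRecord]:
    records = []
    for doc in corpus:
        records.extend(extract(doc, resources))
    return records


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def write_csv(records: Iterable[SpecimenRecord], destination: str | Path) -> int:
    """Write one RFC-4180 row per (report, specimen, lesion); returns the
    number of data rows.  The file appears atomically (temp file + rename)."""
    destination = Path(destination)
    rows = sorted(records, key=SpecimenRecord.key)
    fd, tmp = tempfile.mkstemp(
        dir=str(destination.parent) or ".", prefix=destination.name, suffix=".tmp"
    )
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["report_id", "specimen", "lesion"] + list(RECORD_COLUMNS))
            for rec in rows:
                writer.writerow(rec.as_row())
        os.replace(tmp, destination)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return len(rows)


def write_provenance(resources: Resources, destination: str | Path) -> None:
    Path(destination).write_text(
        json.dumps({"resource_checksums": resources.checksums}, indent=1, sort_keys=True)
        + "\n",
        encoding="utf-8",
    )
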