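"""Seeded generator of BCC histopathology reports with exact gold-standard
annotations and structured records.

The real health-board corpora behind this kind of pipeline are never
shareable, so the generator emulates their canonical shape: accession
number, excision date, clinical details, macroscopic details, microscopic
details, microscopic measurements, report details, requestor and
supplementary report, written in one of a bank of simulated
pathologist styles (header synonyms and casing vary), with a small
fraction of reports using a fixed structured proforma.  Reports carry on
average ~1.5 BCC lesions (one lesion per labelled specimen).

Every planted mention is recorded as a gold standoff annotation whose
features mirror what the shipped cascade extracts, plus a structured
:class:`GoldRecord` per lesion, so end-to-end extraction can be scored
against a known truth.  Generation is deterministic: each document draws
from its own counter-based random stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationSet, Corpus, Document

SITES = [
    "cheek", "nose", "nasal tip", "forehead", "temple", "scalp", "ear",
    "neck", "back", "chest", "shoulder", "arm", "hand", "leg", "eyebrow",
    "lip", "chin",
]
SUBTYPES = [
    "nodular", "superficial", "infiltrative", "micronodular", "morphoeic",
    "basosquamous", "cystic", "adenoid",
]
SPECIMEN_TYPES = ["Skin ellipse", "Ellipse of skin", "Punch biopsy", "Shave biopsy"]
DEPARTMENTS = ["Dermatology", "Plastic Surgery", "General Practice", "Oncology"]
LESION_KINDS = ["Lesion", "Nodule", "Papule", "Plaque"]
FACTORS = [
    ("perineural invasion", "perineural_invasion"),
    ("lymphovascular invasion", "lymphovascular_invasion"),
    ("ulceration", "ulceration"),
]
SURNAMES = [
    "Smith", "Jones", "Williams", "Evans", "Thomas", "Davies", "Roberts",
    "Lewis", "Hughes", "Morgan", "Griffiths", "Owen", "Rees", "Jenkins",
    "Powell", "Price", "Morris", "James", "Edwards", "Phillips",
]
BCC_CONCEPT = "C0007117"

_HEADER_SYNONYMS = {
    "AccessionNumber": ["Accession No", "Accession Number", "Lab No", "Lab Number"],
    "ExcisionDate": ["Excision date", "Date of excision"],
    "ClinicalDetails": ["Clinical details", "Clinical history", "Clinical information"],
    "MacroscopicDetails": ["Macroscopic details", "Macroscopy", "Macroscopic description"],
    "MicroscopicDetails": ["Microscopic details", "Microscopy", "Histology"],
    "MicroscopicMeasurements": ["Microscopic measurements", "Tumour measurements"],
    "ReportDetails": ["Report details"],
    "Requestor": ["Requested by", "Requestor", "Referring clinician"],
    "SupplementaryReport": ["Supplementary report"],
}

# the proforma puts section content on the header line; prose styles break
# the line after the header, so this substring marks template reports only
PROFORMA_MARKER = "CLINICAL DETAILS: "

FILLER_SENTENCES = [
    "Sections examined at multiple levels.",
    "The appearances are typical.",
    "Paraffin blocks retained.",
]


@dataclass
class GenerationConfig:
    n_reports: int = 200
    lesion_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    template_fraction: float = 0.07
    negation_rate: float = 0.7
    style_bank: int = 20
    noise: dict | None = None  # {"filler_rate": p}
    seed: int = 0
    # section prevalence (per report)
    excision_date_rate: float = 0.05
    requestor_rate: float = 0.05
    supplementary_rate: float = 0.05
    # per-lesion content rates
    factor_mention_rate: float = 0.8
    residual_disease_rate: float = 0.3
    confined_rate: float = 0.5
    subtype_rate: float = 0.9
    incomplete_excision_rate: float = 0.15
    clinical_query_rate: float = 0.5
    cm_dims_rate: float = 0.2

    def __post_init__(self) -> None:
        total = sum(self.lesion_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("lesion distribution must sum to 1")
        for p in list(self.lesion_distribution.values()) + [
            self.template_fraction, self.negation_rate
        ]:
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class GoldRecord:
    """Planted per-lesion truth mirroring the pipeline's SpecimenRecord."""

    report_id: str
    specimen: str
    lesion_index: int
    values: dict[str, object] = field(default_factory=dict)

    def key(self):
        return (self.report_id, self.specimen, self.lesion_index)


@dataclass
class GeneratedCorpus:
    corpus: Corpus
    records: list[GoldRecord]
    manifest: dict
    surfaces: dict[str, list[tuple[int, int, str]]]  # planted mention spans


class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0

    def add(self, text: str) -> int:
        start = self.pos
        self.parts.append(text)
        self.pos += len(text)
        return start

    def text(self) -> str:
        return "".join(self.parts)


def _fmt(v: float) -> str:
    return f"{v:.1f}"


def _choice(rng, seq):
    return seq[int(rng.integers(len(seq)))]


def _header(label: str, style: int, proforma: bool) -> str:
    if proforma:
        return _HEADER_SYNONYMS[label][0].upper()
    syns = _HEADER_SYNONYMS[label]
    text = syns[style % len(syns)]
    case = style % 3
    if case == 1:
        return text.upper()
    if case == 2:
        return text.title()
    return text


def generate_corpus(config: GenerationConfig) -> GeneratedCorpus:
    """Generate a seeded corpus with gold annotations and records."""
    if config.n_reports <= 0:
        raise ValueError("n_reports must be positive")
    corpus = Corpus()
    records: list[GoldRecord] = []
    surfaces: dict[str, list[tuple[int, int, str]]] = {}
    template_ids: list[str] = []
    lesion_total = 0
    lesion_counts = sorted(config.lesion_distribution)
    lesion_probs = [config.lesion_distribution[k] for k in lesion_counts]

    for i in range(config.n_reports):
        rng = np.random.default_rng([config.seed, i])
        doc_id = f"R{i:04d}"
        proforma = bool(rng.random() < config.template_fraction)
        n_lesions = int(rng.choice(lesion_counts, p=lesion_probs))
        doc, doc_records, doc_surfaces = _generate_report(
            doc_id, rng, config, proforma, n_lesions
        )
        corpus.add(doc)
        records.extend(doc_records)
        surfaces[doc_id] = doc_surfaces
        lesion_total += n_lesions
        if proforma:
            template_ids.append(doc_id)

    digest = hashlib.sha256(
        "\x00".join(d.text for d in corpus).encode("utf-8")
    ).hexdigest()
    manifest = {
        "n_reports": config.n_reports,
        "seed": config.seed,
        "n_lesions": lesion_total,
        "template_report_ids": template_ids,
        "template_fraction_realized": len(template_ids) / config.n_reports,
        "corpus_sha256": digest,
        "layouts": "synthetic reconstructions of canonical report structure",
    }
    return GeneratedCorpus(corpus, records, manifest, surfaces)


def _generate_report(
    doc_id: str,
    rng: np.random.Generator,
    config: GenerationConfig,
    proforma: bool,
    n_lesions: int,
):
    b = _Builder()
    gold: list[tuple[str, int, int, dict]] = []
    planted: list[tuple[int, int, str]] = []
    style = int(rng.integers(config.style_bank))
    filler_rate = (config.noise or {}).get("filler_rate", 0.0)

    def plant(category: str, start: int, end: int, features: dict) -> None:
        gold.append((category, start, end, features))

    def mention(text: str) -> int:
        start = b.add(text)
        planted.append((start, start + len(text), text))
        return start

    doc_values: dict[str, object] = {}

    # --- accession -------------------------------------------------------
    year = int(rng.integers(2016, 2019))
    acc = f"{year % 100:02d}H{int(rng.integers(10000, 100000))}"
    b.add(_header("AccessionNumber", style, proforma) + ": ")
    s = mention(acc)
    plant("AccessionNumber", s, s + len(acc), {"value": acc})
    b.add("\n")
    doc_values["accession_number"] = acc

    # --- excision date ---------------------------------------------------
    has_excision_date = proforma or rng.random() < config.excision_date_rate
    if has_excision_date:
        day, month = int(rng.integers(1, 29)), int(rng.integers(1, 13))
        date = f"{day:02d}/{month:02d}/{year}"
        b.add(_header("ExcisionDate", style, proforma) + ": ")
        s = mention(date)
        plant(
            "ExcisionDate",
            s,
            s + len(date),
            {"day": f"{day:02d}", "month": f"{month:02d}", "year": str(year)},
        )
        b.add("\n")
        doc_values["excision_date"] = f"{year:04d}-{month:02d}-{day:02d}"

    # --- requestor -------------------------------------------------------
    if proforma or rng.random() < config.requestor_rate:
        surname = _choice(rng, SURNAMES)
        dept = _choice(rng, DEPARTMENTS)
        b.add(_header("Requestor", style, proforma) + ": ")
        s = mention(f"Dr {surname}, {dept}")
        plant(
            "Requestor",
            s,
            b.pos,
            {"name": f"dr {surname.lower()}", "department": dept.lower()},
        )
        b.add("\n")
        doc_values["requestor_name"] = f"dr {surname.lower()}"
        doc_values["requestor_department"] = dept.lower()

    # --- clinical details ------------------------------------------------
    b.add(_header("ClinicalDetails", style, proforma) + ":")
    b.add(" " if proforma else "\n")
    lesion_kw = _choice(rng, LESION_KINDS)
    site = _choice(rng, SITES)
    lateral = rng.random() < 0.7
    laterality = _choice(rng, ["left", "right"]) if lateral else None
    s = mention(
        f"{lesion_kw} on {laterality + ' ' if laterality else ''}{site}"
    )
    clin_feats = {"lesion_type": lesion_kw.lower(), "site": site}
    if laterality:
        clin_feats["laterality"] = laterality
    plant("ClinicalDetails", s, b.pos, clin_feats)
    b.add(".")
    doc_values["site"] = site
    doc_values["lesion_type"] = lesion_kw.lower()
    if laterality:
        doc_values["laterality"] = laterality
    if rng.random() < config.clinical_query_rate:
        b.add(" ?")
        s = mention("BCC")
        plant("ClinicalDetails", s, b.pos, {"tag": "bcc", "concept": BCC_CONCEPT})
        b.add(".")
        doc_values["clinical_query"] = "bcc"
    b.add("\n")

    labelled = n_lesions > 1 or rng.random() < 0.5
    labels = [chr(ord("A") + k) for k in range(n_lesions)] if labelled else None

    # --- macroscopic details --------------------------------------------
    b.add(_header("MacroscopicDetails", style, proforma) + ":")
    b.add(" " if proforma else "\n")
    macro: dict[str, dict] = {}
    for k in range(n_lesions):
        lab = labels[k] if labels else "1"
        if labels:
            b.add(f"{labels[k]}. ")
        spec_type = _choice(rng, SPECIMEN_TYPES)
        dims = sorted(rng.integers(3, 31, size=3), reverse=True)
        use_cm = rng.random() < config.cm_dims_rate
        if use_cm:
            dim_strs = [_fmt(d / 10.0) for d in dims]
            unit = "cm"
        else:
            dim_strs = [str(int(d)) for d in dims]
            unit = "mm"
        s = mention(f"{spec_type} {dim_strs[0]} x {dim_strs[1]} x {dim_strs[2]} {unit}")
        plant(
            "MacroscopicDetails",
            s,
            b.pos,
            {
                "specimen_type": spec_type.lower(),
                "dim1": dim_strs[0],
                "dim2": dim_strs[1],
                "dim3": dim_strs[2],
                "unit": unit,
            },
        )
        b.add(" bearing a pearly nodule.")
        macro[lab] = {
            "specimen_type": spec_type.lower(),
            "specimen_dim1_mm": float(dims[0]),
            "specimen_dim2_mm": float(dims[1]),
            "specimen_dim3_mm": float(dims[2]),
        }
        b.add("\n")

    # --- microscopic details --------------------------------------------
    b.add(_header("MicroscopicDetails", style, proforma) + ":")
    b.add(" " if proforma else "\n")
    lesions: list[tuple[str, dict]] = []
    for k in range(n_lesions):
        lab = labels[k] if labels else "1"
        lesion_vals: dict[str, object] = {}
        if labels:
            b.add(f"{labels[k]}. ")
        use_subtype = rng.random() < config.subtype_rate
        if use_subtype:
            subtype = _choice(rng, SUBTYPES)
            surface = subtype.capitalize() + " basal cell carcinoma"
            s = mention(surface)
            plant(
                "MicroscopicDetails",
                s,
                b.pos,
                {"tag": "bcc", "concept": BCC_CONCEPT, "subtype": subtype},
            )
            lesion_vals["subtype"] = subtype
        else:
            s = mention("Basal cell carcinoma")
            plant(
                "MicroscopicDetails", s, b.pos, {"tag": "bcc", "concept": BCC_CONCEPT}
            )
        b.add(".")
        lesion_vals["tag"] = "bcc"

        for surface_factor, factor_key in FACTORS:
            if rng.random() >= config.factor_mention_rate:
                continue
            negated = rng.random() < config.negation_rate
            if negated:
                b.add(" No ")
                s = mention(surface_factor)
                plant(
                    "MicroscopicDetails",
                    s,
                    b.pos,
                    {"factor": factor_key, "negated": True},
                )
                b.add(" seen.")
                lesion_vals[factor_key] = "negated"
            else:
                b.add(" ")
                s = mention(surface_factor.capitalize())
                plant(
                    "MicroscopicDetails",
                    s,
                    b.pos,
                    {"factor": factor_key, "affirmed": True},
                )
                b.add(" present.")
                lesion_vals[factor_key] = "affirmed"

        if rng.random() < config.residual_disease_rate:
            b.add(" There was no ")
            s = mention("residual disease")
            plant(
                "MicroscopicDetails",
                s,
                b.pos,
                {"factor": "residual_disease", "negated": True},
            )
            b.add(".")
            lesion_vals["residual_disease"] = "negated"

        if rng.random() < config.confined_rate:
            b.add(" ")
            s = mention("Tumour")
            plant(
                "MicroscopicDetails", s, b.pos, {"factor": "tumour", "affirmed": True}
            )
            b.add(" confined to the dermis.")
            lesion_vals["tumour_confined"] = "affirmed"

        incomplete = rng.random() < config.incomplete_excision_rate
        b.add(" ")
        status_surface = "Incompletely excised" if incomplete else "Completely excised"
        s = mention(status_surface)
        plant(
            "MicroscopicDetails",
            s,
            b.pos,
            {"completeness_of_excision": "incomplete" if incomplete else "complete"},
        )
        b.add(".")
        lesion_vals["completeness_of_excision"] = (
            "incomplete" if incomplete else "complete"
        )
        if rng.random() < filler_rate:
            b.add(" " + _choice(rng, FILLER_SENTENCES))
        b.add("\n")
        lesions.append((lab, lesion_vals))

    # --- microscopic measurements ---------------------------------------
    b.add(_header("MicroscopicMeasurements", style, proforma) + ":")
    b.add(" " if proforma else "\n")
    for k in range(n_lesions):
        lab, lesion_vals = lesions[k]
        if labels:
            b.add(f"{labels[k]}. ")
        first = True
        for axis_surface, axis_key, col in (
            ("Tumour thickness", "thickness", "tumour_thickness_mm"),
            ("Tumour diameter", "diameter", "tumour_diameter_mm"),
            ("Peripheral clearance", "peripheral", "peripheral_clearance_mm"),
            ("Deep clearance", "deep", "deep_clearance_mm"),
        ):
            if rng.random() >= 0.9:
                continue
            value = _fmt(float(rng.uniform(0.2, 9.9 if "clearance" in col else 14.9)))
            clock = None
            if axis_key == "peripheral" and rng.random() < 0.7:
                clock = int(rng.integers(1, 13))
            if not first:
                b.add(" ")
            first = False
            phrase = f"{axis_surface} {value} mm"
            if clock is not None:
                phrase += f" at {clock} o'clock"
            s = mention(phrase)
            feats = {"axis": axis_key, "value": value, "unit": "mm"}
            if clock is not None:
                feats["clock"] = str(clock)
            plant("MicroscopicMeasurements", s, b.pos, feats)
            b.add(".")
            lesion_vals[col] = float(value)
            if clock is not None:
                lesion_vals["peripheral_clearance_clock"] = clock
        if first:  # no measurement survived the coin flips; keep prose valid
            b.add("Not assessable.")
        b.add("\n")

    # --- supplementary report -------------------------------------------
    has_supplementary = rng.random() < config.supplementary_rate
    if proforma or has_supplementary:
        b.add(_header("SupplementaryReport", style, proforma) + ": ")
        if has_supplementary:
            b.add("Immunostains confirm ")
            s = mention("basal cell carcinoma")
            plant(
                "SupplementaryReport", s, b.pos, {"tag": "bcc", "concept": BCC_CONCEPT}
            )
            b.add(".")
            doc_values["supplementary_finding"] = "bcc"
        else:
            b.add("None.")
        b.add("\n")

    # --- report details --------------------------------------------------
    surname = _choice(rng, SURNAMES)
    rday, rmonth = int(rng.integers(1, 29)), int(rng.integers(1, 13))
    rdate = f"{rday:02d}/{rmonth:02d}/{year}"
    b.add(_header("ReportDetails", style, proforma) + ": Authorised by ")
    s = mention(f"Dr {surname} on {rdate}")
    plant(
        "ReportDetails",
        s,
        b.pos,
        {
            "author": f"dr {surname.lower()}",
            "day": f"{rday:02d}",
            "month": f"{rmonth:02d}",
            "year": str(year),
        },
    )
    b.add(".\n")
    doc_values["report_author"] = f"dr {surname.lower()}"
    doc_values["report_date"] = f"{year:04d}-{rmonth:02d}-{rday:02d}"

    doc = Document(doc_id, b.text())
    gold_set = doc.annset("gold")
    for category, start, end, features in sorted(
        gold, key=lambda g: (g[1], -g[2], g[0])
    ):
        gold_set.add(category, start, end, features)

    doc_records = []
    for lab, lesion_vals in sorted(lesions, key=lambda lv: lv[0]):
        values = dict(doc_values)
        values.update(macro.get(lab, {}))
        values.update(lesion_vals)
        doc_records.append(GoldRecord(doc_id, lab, 0, values))
    return doc, doc_records, planted


# ---------------------------------------------------------------------------
# Annotator simulation
# ---------------------------------------------------------------------------

def generate_annotator_pair(
    corpus: Corpus,
    disagreement_rate: float,
    seed: int,
    gold_label: str = "gold",
    kinds: tuple[str, ...] = ("drop", "jitter", "flip"),
    labels: tuple[str, str] = ("annotatorA", "annotatorB"),
) -> None:
    """Attach two independently perturbed copies of the gold set to every
    document, simulating imperfect human annotators for the IAA stack."""
    if not (0 <= disagreement_rate <= 1):
        raise ValueError("disagreement rate must lie in [0, 1]")
    for di, doc in enumerate(corpus):
        gold = doc.annset(gold_label, create=False)
        for ai, label in enumerate(labels):
            rng = np.random.default_rng([seed, di, ai])
            aset = doc.annset(label)
            for ann in gold:
                if rng.random() >= disagreement_rate:
                    aset.add(ann.category, ann.start, ann.end, dict(ann.features))
                    continue
                kind = kinds[int(rng.integers(len(kinds)))]
                if kind == "drop":
                    continue
                if kind == "jitter":
                    delta = int(rng.integers(1, 4))
                    new_end = min(ann.end + delta, len(doc.text))
                    if new_end == ann.end:
                        new_end = max(ann.start + 1, ann.end - delta)
                    aset.add(ann.category, ann.start, new_end, dict(ann.features))
                    continue
                # flip: alter one feature value
                feats = dict(ann.features)
                if feats:
                    name = sorted(feats)[int(rng.integers(len(feats)))]
                    v = feats[name]
                    feats[name] = (not v) if isinstance(v, bool) else f"{v}~alt"
                aset.add(ann.category, ann.start, ann.end, feats)
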