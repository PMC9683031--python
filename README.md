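# bccnlp

Rule-based information extraction for basal cell carcinoma (BCC)
histopathology reports — and the validation machinery such a system needs.

Cancer registries systematically under-count non-melanoma skin cancer
because the details that matter (per-lesion diagnosis, subtype, margin
clearances, prognostic factors) live in free-text pathology reports, not
in coded fields.  `bccnlp` is for health-informatics researchers and
registry engineers who want a transparent, auditable pipeline that turns
those reports into structured per-lesion records, plus the standard
apparatus for validating one: partial-match scoring, inter-annotator
agreement, and a principled answer to "how many reports does my gold
corpus need?".

## What it does

- **Named-entity extraction** over the canonical nine-section report
  structure (accession number, excision date, clinical details,
  macroscopic details, microscopic details, microscopic measurements,
  report details, requestor, supplementary report): gazetteer lookup →
  cascaded pattern rules (a declarative YAML dialect with appelt/first/all
  control, bindings, create/remove actions) → ConText-style negation and
  affirmation with sentence-bounded scopes → per-specimen, per-lesion CSV
  records.  Measurements are normalised to millimetres, including
  dimension triples (`15 x 8 x 4 mm`) and clock positions
  (`peripheral clearance 1 mm at 12 o'clock`).
- **Evaluation**: key/response alignment by exact optimal assignment;
  strict / average / lenient scoring with partial weight w ∈ {0, ½, 1}:

      P = (correct + w·partial) / (correct + spurious + partial)
      R = (correct + w·partial) / (correct + missing + partial)
      F1 = 2PR / (P + R)

  macro (per-document, with 95% CIs) and micro aggregation; token
  confusion matrices, Cohen's κ, positive specific agreement and pairwise
  F1 for inter-annotator agreement.
- **Validation-corpus sizing**: the probability that a token present in
  `d` of `D` reference documents appears in a random sample of `N` is
  hypergeometric, `1 − C(D−d, N)/C(D, N)`; aggregated over a concept
  vocabulary this gives a capture probability, and binary search finds the
  smallest `N` reaching a target (e.g. 90%).
- **Synthetic corpus generation**: seeded, gold-annotated BCC reports
  (~1.5 lesions/report, configurable proforma fraction, 20 writer styles)
  standing in for unshareable clinical corpora, with exact planted spans
  so the pipeline can be scored against a known truth.

## Worked example

```python
from bccnlp import Document, extract, load_resources

report = """\
Lab No: 16H12345
Microscopy:
Nodular basal cell carcinoma. No perineural invasion seen.
Tumour confined to the dermis. Completely excised.
Microscopic measurements:
Tumour thickness 1.2 mm. Peripheral clearance 1 mm at 12 o'clock.
"""
resources = load_resources()
records = extract(Document("example", report), resources)
print(records[0].values)
```

prints (abbreviated):

```
{'accession_number': '16H12345', 'tag': 'bcc', 'subtype': 'nodular',
 'perineural_invasion': 'negated', 'tumour_confined': 'affirmed',
 'completeness_of_excision': 'complete', 'tumour_thickness_mm': 1.2,
 'peripheral_clearance_mm': 1.0, 'peripheral_clearance_clock': 12}
```

`tag: bcc` asserts a confirmed BCC lesion; `perineural_invasion:
negated` means the factor was mentioned and explicitly ruled out;
measurements are in millimetres.  Scoring the pipeline on a 50-report
synthetic corpus (`python examples/score_extraction_against_gold.py`):

```
strict   P=100.0% R=100.0% F1=100.0%  (95% CI on F1: 100.0-100.0, n=50 documents)
average  P=100.0% R=100.0% F1=100.0%  (95% CI on F1: 100.0-100.0, n=50 documents)
lenient  P=100.0% R=100.0% F1=100.0%  (95% CI on F1: 100.0-100.0, n=50 documents)
```

The perfect closure on noise-free synthetic text is a correctness check
of the whole cascade, not a claim about real-world accuracy — see
`docs/methods.md` for what it does and does not show.  The other
examples cover inter-annotator agreement (`interannotator_agreement.py`),
corpus sizing (`size_validation_corpus.py`) and corpus generation
(`generate_synthetic_corpus.py`).

A `bccnlp` console command exposes the same capabilities from the shell:
`bccnlp run`, `bccnlp evaluate`, `bccnlp iaa`, `bccnlp corpus-size`,
`bccnlp synth`, `bccnlp validate-resources`.

## Layout

```
src/bccnlp/            annotation model, preprocessing, gazetteer, rule
                       engine, context detector, pipeline, evaluation,
                       sizing, synthesis, CLI
src/bccnlp/resources/  gazetteers (.lst/.def), rule cascades (YAML),
                       ConText triggers, schema, pipeline config
examples/              one narrative script per capability
tests/                 unit, property and acceptance tests
docs/methods.md        models, parameters, design choices, limitations
```
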