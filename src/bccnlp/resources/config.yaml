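# Pipeline resource configuration
gazetteers: gazetteers/index.def
rules:
  - rules/entities.yaml
cleanup_rules:
  - rules/cleanup.yaml
triggers: triggers.lst
schema: schema.yaml
tokenizer:
  policy: general
context:
  targets: [PrognosticFactor]
  max_window_tokens: null
sections:
  headers:
    AccessionNumber: [accession number, accession no, lab number, lab no]
    ExcisionDate: [excision date, date of excision]
    ClinicalDetails: [clinical details, clinical history, clinical information]
    MacroscopicDetails: [macroscopic details, macroscopic description, macroscopy]
    MicroscopicDetails: [microscopic details, microscopic description, microscopy, histology]
    MicroscopicMeasurements: [microscopic measurements, tumour measurements]
    ReportDetails: [report details]
    Requestor: [requestor, requested by, referring clinician]
    SupplementaryReport: [supplementary report, supplementary]
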