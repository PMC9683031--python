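# Closed extraction schema: the nine canonical entity categories and the
# features each may carry.  Unknown features are rejected at run time.
categories:
  AccessionNumber:
    value: text
  ExcisionDate:
    day: number
    month: number
    year: number
  ClinicalDetails:
    lesion_type: text
    laterality: text
    site: text
    tag: text
    concept: text
    subtype: text
  MacroscopicDetails:
    specimen_type: text
    dim1: number
    dim2: number
    dim3: number
    unit: text
  MicroscopicDetails:
    tag: text
    concept: text
    subtype: text
    factor: text
    negated: boolean
    affirmed: boolean
    completeness_of_excision: text
  MicroscopicMeasurements:
    axis: text
    value: number
    unit: text
    clock: clock
  ReportDetails:
    author: text
    day: number
    month: number
    year: number
  Requestor:
    name: text
    department: text
  SupplementaryReport:
    tag: text
    concept: text
    subtype: text
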