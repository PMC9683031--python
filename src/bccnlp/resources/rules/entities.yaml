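# Main named-entity phase: one rule per report fact, longest-match (appelt)
# control over the Token + Lookup layers.  Covered-text feature copies are
# normalised (lower-cased, whitespace collapsed) unless the action asks for
# the raw text.
phase:
  name: entities
  control: appelt
  input: [Token, Lookup]
rules:
  - name: accession_value
    priority: 50
    pattern:
      - {category: Lookup, features: {majorType: field_label, minorType: accession}}
      - {category: Token, text: ":"}
      - {category: Token, text: {regex: "^\\d{2}[A-Z]\\d{5}$"}, bind: v}
    actions:
      - create:
          category: AccessionValue
          span: v
          features:
            value: {rawtext: v}

  - name: excision_date
    priority: 50
    pattern:
      - {category: Lookup, features: {majorType: field_label, minorType: excision_date}}
      - {category: Token, text: ":", quantifier: optional}
      - {category: Token, text: {regex: "^\\d{1,2}$"}, bind: d}
      - {category: Token, text: "/"}
      - {category: Token, text: {regex: "^\\d{1,2}$"}, bind: m}
      - {category: Token, text: "/"}
      - {category: Token, text: {regex: "^\\d{4}$"}, bind: y}
    actions:
      - create:
          category: DateOfExcision
          span: [d, y]
          features:
            day: {rawtext: d}
            month: {rawtext: m}
            year: {rawtext: y}

  - name: requestor_detail
    priority: 40
    pattern:
      - {category: Lookup, features: {majorType: field_label, minorType: requestor}}
      - {category: Token, text: ":", quantifier: optional}
      - {category: Token, text: {regex: "^(Dr|Mr|Mrs|Ms|Prof)$"}, bind: t}
      - {category: Token, text: {regex: "^[A-Z][a-z]+$"}, bind: n}
      - {category: Token, text: ","}
      - {category: Lookup, features: {majorType: department}, bind: dep}
    actions:
      - create:
          category: RequestorDetail
          span: [t, dep]
          features:
            name: {text_span: [t, n]}
            department: {text: dep}

  - name: report_authorisation
    priority: 40
    pattern:
      - {category: Lookup, features: {majorType: field_label, minorType: report}}
      - {category: Token, text: {regex: "^(Dr|Mr|Mrs|Ms|Prof)$"}, bind: t}
      - {category: Token, text: {regex: "^[A-Z][a-z]+$"}, bind: n}
      - {category: Token, text: {regex: "^on$"}}
      - {category: Token, text: {regex: "^\\d{1,2}$"}, bind: d}
      - {category: Token, text: "/"}
      - {category: Token, text: {regex: "^\\d{1,2}$"}, bind: m}
      - {category: Token, text: "/"}
      - {category: Token, text: {regex: "^\\d{4}$"}, bind: y}
    actions:
      - create:
          category: ReportAuthorisation
          span: [t, y]
          features:
            author: {text_span: [t, n]}
            day: {rawtext: d}
            month: {rawtext: m}
            year: {rawtext: y}

  - name: lesion_description
    priority: 30
    pattern:
      - {category: Lookup, features: {majorType: lesion_kw}, bind: lk}
      - {category: Token, text: {regex: "^(on|of)$"}}
      - {category: Token, text: {regex: "^the$"}, quantifier: optional}
      - {category: Lookup, features: {majorType: laterality}, quantifier: optional, bind: lat}
      - {category: Lookup, features: {majorType: site}, bind: site}
    actions:
      - create:
          category: LesionDescription
          span: match
          features:
            lesion_type: {text: lk}
            laterality: {text: lat}
            site: {text: site}

  - name: specimen_description
    priority: 30
    pattern:
      - {category: Lookup, features: {majorType: specimen_type}, bind: st}
      - {category: Token, features: {kind: number}, bind: d1}
      - {category: Token, text: {regex: "^[xX]$"}}
      - {category: Token, features: {kind: number}, bind: d2}
      - {category: Token, text: {regex: "^[xX]$"}}
      - {category: Token, features: {kind: number}, bind: d3}
      - {category: Lookup, features: {majorType: unit}, bind: unit}
    actions:
      - create:
          category: SpecimenDescription
          span: match
          features:
            specimen_type: {text: st}
            dim1: {text: d1}
            dim2: {text: d2}
            dim3: {text: d3}
            unit: {text: unit}

  - name: measurement
    priority: 30
    pattern:
      - {category: Lookup, features: {majorType: measure_axis}, bind: ax}
      - {category: Token, features: {kind: number}, bind: val}
      - {category: Lookup, features: {majorType: unit}, bind: unit}
      - {category: Token, text: {regex: "^at$"}, quantifier: optional}
      - {category: Token, features: {kind: number}, quantifier: optional, bind: clk}
      - {category: Lookup, features: {majorType: clock_marker}, quantifier: optional, bind: cm}
    actions:
      - create:
          category: Measurement
          span: match
          features:
            axis: {feature: [ax, minorType]}
            value: {text: val}
            unit: {text: unit}
            clock: {text: clk}

  - name: diagnosis
    priority: 20
    pattern:
      - {category: Lookup, features: {majorType: subtype}, quantifier: optional, bind: sub}
      - {category: Lookup, features: {majorType: diagnosis}, bind: diag}
    actions:
      - create:
          category: Diagnosis
          span: match
          features:
            tag: {feature: [diag, minorType]}
            concept: {feature: [diag, conceptCode]}
            subtype: {text: sub}

  - name: prognostic_factor
    priority: 10
    pattern:
      - {category: Lookup, features: {majorType: prognostic}, bind: pf}
    actions:
      - create:
          category: PrognosticFactor
          span: pf
          features:
            factor: {feature: [pf, minorType]}

  - name: excision_status
    priority: 10
    pattern:
      - {category: Lookup, features: {majorType: excision_status}, bind: ex}
    actions:
      - create:
          category: ExcisionStatus
          span: ex
          features:
            completeness_of_excision: {feature: [ex, minorType]}
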