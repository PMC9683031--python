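# Post-polarity cleanup: remove annotations that carry no information.
# A bare "tumour" mention that was neither negated nor affirmed by its
# context (e.g. inside an unrelated phrase) is dropped from the output.
phase:
  name: cleanup
  control: all
  input: [PrognosticFactor]
rules:
  - name: drop_bare_tumour_mention
    priority: 0
    pattern:
      - category: PrognosticFactor
        features:
          factor: tumour
          negated: {absent: true}
          affirmed: {absent: true}
        bind: t
    actions:
      - remove: t
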