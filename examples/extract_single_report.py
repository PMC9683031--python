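"""Extract structured data from one histopathology report.

Builds a short free-text BCC report, runs the full cascade (tokens ->
sections -> gazetteer lookups -> pattern rules -> negation/affirmation)
and prints the per-lesion record.  Values such as 'negated' mean the
factor was mentioned and explicitly ruled out in the text.
"""

from bccnlp import Document, extract, load_resources

REPORT = """\
Lab No: 16H12345
Clinical details:
Lesion on left cheek. ?BCC.
Macroscopy:
Skin ellipse 15 x 8 x 4 mm bearing a pearly nodule.
Microscopy:
Nodular basal cell carcinoma. No perineural invasion seen.
Tumour confined to the dermis. Completely excised.
Microscopic measurements:
Tumour thickness 1.2 mm. Peripheral clearance 1 mm at 12 o'clock.
"""

resources = load_resources()
doc = Document("example", REPORT)
records = extract(doc, resources)

print("system annotations:")
for ann in doc.annset("system"):
    print(f"  {ann.category:24s} {doc.text[ann.start:ann.end]!r:45s} {ann.features}")

print("\nper-lesion record:")
for rec in records:
    for k, v in sorted(rec.values.items()):
        print(f"  {k:28s} {v}")
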