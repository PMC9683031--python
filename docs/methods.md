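# Methods

`bccnlp` is a rule-based information-extraction system for basal cell
carcinoma (BCC) histopathology reports, together with the machinery such a
system needs to be validated: partial-match scoring, inter-annotator
agreement statistics, a capture-probability method for sizing a validation
corpus, and a gold-annotated synthetic report generator.  This note
documents the models and procedures, the parameters that matter, and the
design choices made where the design was genuinely open.

## The extraction model

A report is processed as a cascade over standoff annotations (typed
character spans with flat feature maps, 0-based half-open offsets):

1. **Tokenisation** ("general" policy): maximal alphanumeric runs, with
   decimal numbers kept whole, and single punctuation characters; each
   token carries a `kind` feature (`word`/`number`/`punct`).
2. **Sentence splitting**: boundaries at newline runs and at `.?!` followed
   by whitespace.  Hard abbreviations (`Dr`, `Mr`, ...) never end a
   sentence; the unit abbreviations `mm.`/`cm.` end one only when the next
   character starts a new sentence (upper-case letter or digit).  This
   compromise keeps `Diameter 1.2 mm. Clear.` two sentences while not
   splitting inside running measurement prose.  Decimal points are never
   boundaries because they are not followed by whitespace.
3. **Section segmentation**: the canonical nine-section report structure
   (accession number, excision date, clinical details, macroscopic details,
   microscopic details, microscopic measurements, report details,
   requestor, supplementary report).  A configurable, case-insensitive
   synonym list is matched at line start; a header opens a section running
   to the next header; text before the first header — or a headerless
   report — is `ReportDetails`.
4. **Gazetteer lookup**: tab-separated lexicons (term, majorType,
   minorType, conceptCode), compiled to a longest-match scanner.  Matches
   are anchored on token boundaries (so `carcinoma` never fires inside
   `carcinomatous`), case-insensitive unless an entry opts out, and only
   the longest match per start offset is emitted; overlapping matches with
   different starts are all kept.  Concept codes are opaque strings
   (UMLS-style CUIs in the shipped lexicons); no terminology service is
   consulted.
5. **Pattern rules**: a declarative YAML dialect over annotation
   sequences.  A rule's left side is a list of elements (category, feature
   predicates, regex over covered text, quantifier `one`/`optional`/
   `star`/`plus`/`range`, optional binding); its right side creates
   annotations (features copied from bindings — normalised covered text,
   raw text, or another annotation's feature — or literal) or removes
   bound annotations.  Phases run under `appelt` control (longest match
   wins; ties break by priority, then declaration order; matched regions
   are consumed), `first`, or `all` (every match fires, nothing consumed;
   matches are collected against the phase-start annotation snapshot and
   applied in document order).  Sequence adjacency means "the next
   annotation starts at the first annotation-start offset reachable across
   whitespace only".  Quantifiers are greedy with backtracking.  All rule
   files are validated at load time (unknown keys, unbound labels, bad
   quantifiers, duplicate rule names) with file and rule diagnostics.
6. **Polarity (ConText-style)**: trigger terms open negation or
   affirmation scopes forward (to sentence end), backward (to sentence
   start) or bidirectionally, closed early by termination terms or an
   optional token-window cap (default unlimited, the published ConText
   default).  Pseudo-triggers ("no increase") suppress the trigger they
   contain via the same longest-match-per-start rule the gazetteer uses.
   Targets wholly inside a scope get `negated=True` or `affirmed=True`;
   negation takes precedence, so the two are never both true.  Scopes
   never cross sentence boundaries.  Only these two axes are modelled;
   temporality and experiencer are out of scope for pathology reports,
   which describe the current specimen of the patient at hand.
7. **Cleanup**: a second, post-polarity cascade pass removes annotations
   that carry no information once context is known (the shipped rule drops
   bare "tumour" mentions that were neither negated nor affirmed).  The
   cleanup pass runs after polarity detection because its conditions read
   the polarity features.
8. **Entity labelling and records**: cascade rules emit intermediate
   categories (`Diagnosis`, `PrognosticFactor`, `Measurement`, ...); each
   surviving intermediate is re-labelled with its enclosing section's
   label, so the final inventory is exactly the nine canonical entities
   and section attribution holds by construction.  Records are grouped per
   specimen (labels such as `A.`/`1.` at line starts inside the
   macroscopy/microscopy/measurement sections open a specimen context;
   unlabelled reports get the implicit specimen `1`) and per lesion (one
   per confirmed diagnosis annotation).  Output is RFC-4180 CSV, one row
   per (report, specimen, lesion), fixed column order, written atomically,
   with a provenance file of resource checksums alongside.

Measurements are parsed from covered text: `<num> mm|cm`, dimension
triples `a x b x c mm` (unit distributes), qualifiers (`less than`, `<`,
`at least`, ...) and clock positions (`at 12 o'clock`).  Centimetres are
normalised to millimetres (×10).  Unparseable numerics yield an empty
result and a log line, never an exception.

The schema is closed: the nine categories and their allowed features are
declared in `resources/schema.yaml` and unknown features are rejected at
run time.  The full entity inventory of the original deployment is not
public; the shipped schema covers every entity and feature the study
design names (diagnosis tag and subtype, prognostic factors, completeness
of excision, tumour thickness/diameter, peripheral/deep clearance with
clock position, specimen dimensions, dates, accession, requestor) and is
user-extensible through the YAML.

## Scoring

Alignment of a key (gold) and response (system) set is per category.  A
pair is *correct* when coextensive and feature-compatible, *partial* when
merely overlapping; compatibility is inclusion (every key feature present
in the response with an equal normalised value).  Unmatched key
annotations are *missing*, unmatched responses *spurious*.  The pairing is
an exact lexicographic optimum — maximise correct pairs, then partial
pairs — solved as a linear assignment problem (coextensive edges weighted
`min(nk, nr) + 1`, overlap edges 1, so the correct count always dominates).
A greedy longest-overlap pairing was considered and rejected: it is not
always optimal (two short overlaps can beat one long one), and the
assignment formulation is what the brute-force oracle in the test suite
checks against.

Scores follow the partial-weight convention: strict `w=0`, average
`w=1/2`, lenient `w=1`, with

    P = (correct + w*partial) / (correct + spurious + partial)
    R = (correct + w*partial) / (correct + missing + partial)

and F1 their harmonic mean.  A zero denominator scores 1 when the other
side is also empty (correctly extracting nothing) and 0 otherwise.  Corpus
aggregation is *macro* (mean of per-document scores, counts pooled across
categories within a document; 95% CI by normal approximation, bootstrap
available via `ci_method="bootstrap"`) or *micro* (scores on summed
counts); both are computed.  Per-category macro averages skip documents
where the category appears on neither side, so empty documents do not
inflate a category's score.

Inter-annotator agreement: tokens are labelled by the longest covering
annotation (ties to the schema-earlier category), giving a confusion
matrix over categories plus `NONE`.  Cohen's kappa is reported on
annotated tokens (the `NONE`/`NONE` cell zeroed) and on all tokens;
positive specific agreement per category is `2·both / (first + second)`
with `0/0 = 1`; pairwise F1 pools aligned counts over categories and is
symmetric under role swap (the swap exchanges missing and spurious).  With
a gold consensus available, the per-category difference between each
annotator's F1 against gold is also reported.

## Validation-corpus sizing

For a token present in `d` of `D` reference documents, the probability
that a uniform without-replacement sample of `N` documents contains it is
hypergeometric: `1 − C(D−d, N)/C(D, N)`, computed in log space
(`gammaln`).  A without-replacement model is used because validation
documents are sampled, not re-drawn.  The corpus-level capture probability
aggregates per-token probabilities over the concept vocabulary (the
capture-policy tokens of the concept term list, i.e. alphanumeric
sequences beginning with a letter — digit-initial runs are not tokens
under this policy).  Two aggregations ship: the mean per-token probability
(default) and the fraction of tokens reaching a per-token threshold; the
exact aggregation used by prior work is not public, so both are labelled
reconstructions and the choice is logged in the output.  The smallest `N`
reaching a target is found by binary search, valid because capture is
non-decreasing in `N`; the test suite checks it against a linear scan.

## The synthetic generator

Real health-board histopathology corpora cannot be shared, so the
generator stands in for them.  Its defaults encode the study conditions
this kind of validation is run under: 200 reports; lesions per report
drawn from {1: 0.6, 2: 0.3, 3: 0.1} (mean 1.5, one lesion per labelled
specimen); 7% structured-proforma reports; 20 simulated writer styles
(header synonym and casing choices); excision-date, requestor and
supplementary-report sections present in ~5% of reports each (these
fields are rare in routine reports, which is why their printed counts in
validation studies are small); prognostic factors mentioned at rate 0.8
and negated at rate 0.7 (perineural and lymphovascular invasion are
usually explicitly absent in BCC reports); subtype stated at rate 0.9;
incomplete excision at 0.15; thickness/diameter/clearance values drawn
uniformly within physiologic ranges (thickness 0.2–14.9 mm, clearances
0.2–9.9 mm) and written to one decimal; specimen dimensions 3–30 mm,
written in centimetres 20% of the time.  Every document draws from its
own counter-based random stream (`default_rng([seed, doc_index])`), so
corpora are reproducible under any generation order.

Template prose is built from the same lexicons the gazetteers ship, and
the gold annotations' features are constructed to mirror what the cascade
extracts.  Running the pipeline on a noise-free generated corpus therefore
scores P = R = F1 = 1 by construction — that closure is a correctness
check of the whole pipeline (offsets, rules, polarity, sectioning, record
assembly), not a claim about real-world accuracy.  What passing does not
show: robustness to out-of-lexicon vocabulary, typographical noise,
unseen report layouts, or genuinely ambiguous language; real deployments
of rule-based systems lose tens of F1 points between a training and an
unseen-writer validation corpus, and nothing here simulates that error
profile.  An optional noise setting inserts neutral filler sentences; an
annotator-pair simulator perturbs gold (drops, span jitter, feature
flips) at a configurable disagreement rate to exercise the IAA stack.

## Numerical and degenerate-input choices

- Offsets 0-based half-open; annotation order start-ascending,
  end-descending (longest first); empty spans forbidden.
- Feature values are scalars; covered-text copies are lower-cased with
  whitespace collapsed unless raw text is requested; value comparison in
  scoring treats numeric-looking strings numerically.
- Empty documents are rejected before any resource is touched; resource
  validation failures abort before any document is processed.
- `min_sample_size` with an unreachable target raises (defensively —
  unreachable only if the frequency table violates its invariants).
- Kappa with chance agreement 1 is defined as 1 when observed agreement
  is 1, else 0.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full pipeline on 200-report
corpora, size validation sets from 1,000-report reference corpora,
enumerate capture probabilities exhaustively up to D = 12, use 10,000
Monte-Carlo draws, and check alignment against brute force on 500 random
documents with up to six annotations per side.  These sizes make the
whole suite run in well under a minute on one CPU while keeping every
statistical check at conventional power.

## Known limitations

- The rule dialect has element-level quantifiers only (no group closure)
  and no embedded code on the right-hand side.
- The shipped cascade is a reconstruction sized to the shipped lexicons;
  it is not a drop-in for any production grammar, and its perfect closure
  holds only on text drawn from those lexicons.
- Macro averaging of documents that lack a category entirely is a
  convention (skip), and other conventions would change per-category
  macro values on sparse categories.
- De-identification, HL7/FHIR ingestion and non-BCC schemas are out of
  scope.
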