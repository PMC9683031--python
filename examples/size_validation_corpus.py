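"""How many reports does a validation corpus need?

A token occurring in d of D reference documents is captured by a random
sample of N documents with hypergeometric probability
1 - C(D-d, N) / C(D, N).  Averaging over the tokens of the concept
vocabulary gives a corpus-level capture probability; the smallest N
reaching the target (here 90%) is the recommended validation-set size.
"""

from bccnlp import GenerationConfig, generate_corpus
from bccnlp.gazetteer import read_gazetteer_index
from bccnlp.pipeline import DEFAULT_RESOURCE_DIR
from bccnlp.sizing import corpus_capture, doc_frequency_table, min_sample_size

reference = generate_corpus(GenerationConfig(n_reports=1000, seed=123))
gazetteers = read_gazetteer_index(DEFAULT_RESOURCE_DIR / "gazetteers" / "index.def")
concept_terms = [e.term for g in gazetteers for e in g.entries]

table = doc_frequency_table((d.text for d in reference.corpus), concept_terms)
n90 = min_sample_size(table, target=0.90)
estimate = corpus_capture(table, n90)

print(f"concept tokens tracked:      {len(table)}")
print(f"reference corpus size D:     {table[0].corpus_size}")
print(f"N for 90% capture:           {n90}")
print(f"capture probability at N:    {100*estimate.overall:.1f}%")
print("\nfive hardest tokens at that N:")
for tok, p in sorted(estimate.per_token.items(), key=lambda kv: kv[1])[:5]:
    print(f"  {tok:16s} {100*p:5.1f}%")
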