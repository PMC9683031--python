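import pytest

from bccnlp import GenerationConfig, extract, generate_corpus, load_resources


@pytest.fixture(scope="session")
def resources():
    return load_resources()


@pytest.fixture(scope="session")
def small_generated(resources):
    """A 40-report noise-free synthetic corpus with the pipeline already run."""
    gen = generate_corpus(GenerationConfig(n_reports=40, seed=11))
    records = []
    for doc in gen.corpus:
        records.extend(extract(doc, resources))
    return gen, records
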