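"""Hypergeometric capture probability and validation-set sizing."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bccnlp.sizing import (
    SizingError,
    TokenDocFrequency,
    corpus_capture,
    doc_frequency_table,
    min_sample_size,
    token_capture_probability,
)


def _enumerate_capture(d, cap_d, n):
    """Oracle: exact capture probability by enumerating every N-subset."""
    docs = range(cap_d)
    bearing = set(range(d))
    total = hit = 0
    for combo in itertools.combinations(docs, n):
        total += 1
        if bearing & set(combo):
            hit += 1
    return hit / total if total else 0.0


def test_whole_corpus_sample_always_captures():
    assert token_capture_probability(TokenDocFrequency("t", 5, 10), 10) == 1.0


def test_zero_sample_never_captures():
    assert token_capture_probability(TokenDocFrequency("t", 5, 10), 0) == 0.0


def test_two_document_sample_matches_enumeration():
    # d=5, D=10, N=2: 1 - C(5,2)/C(10,2) = 1 - 10/45
    p = token_capture_probability(TokenDocFrequency("t", 5, 10), 2)
    assert p == pytest.approx(1 - 10 / 45)
    assert p == pytest.approx(_enumerate_capture(5, 10, 2))


def test_sample_larger_than_corpus_rejected():
    with pytest.raises(SizingError):
        token_capture_probability(TokenDocFrequency("t", 5, 10), 11)


def test_doc_frequency_bounds_enforced():
    with pytest.raises(SizingError):
        TokenDocFrequency("t", 0, 10)
    with pytest.raises(SizingError):
        TokenDocFrequency("t", 11, 10)


def test_analytic_equals_enumeration_for_small_corpora():
    for cap_d in (5, 8):
        for d in range(1, cap_d + 1):
            for n in range(0, cap_d + 1):
                analytic = token_capture_probability(
                    TokenDocFrequency("t", d, cap_d), n
                )
                assert analytic == pytest.approx(
                    _enumerate_capture(d, cap_d, n), abs=1e-12
                )


def test_mean_aggregation_example():
    # tokens with capture 0.6 and 1.0 -> overall 0.8: construct exactly
    f_rare = TokenDocFrequency("rare", 4, 10)
    f_common = TokenDocFrequency("common", 10, 10)
    n = 2
    p_rare = token_capture_probability(f_rare, n)
    est = corpus_capture([f_rare, f_common], n)
    assert est.overall == pytest.approx((p_rare + 1.0) / 2)


def test_fraction_aggregation():
    f1 = TokenDocFrequency("a", 10, 10)
    f2 = TokenDocFrequency("b", 1, 10)
    est = corpus_capture([f1, f2], 2, aggregation="fraction", threshold=0.9)
    assert est.overall == 0.5


def test_inconsistent_corpus_sizes_rejected():
    with pytest.raises(SizingError):
        corpus_capture(
            [TokenDocFrequency("a", 1, 10), TokenDocFrequency("b", 1, 12)], 2
        )


@settings(max_examples=100, derandomize=True)
@given(
    st.integers(2, 40).flatmap(
        lambda cap_d: st.tuples(
            st.just(cap_d),
            st.lists(st.integers(1, cap_d), min_size=1, max_size=6),
            st.integers(0, cap_d - 1),
        )
    )
)
def test_capture_is_monotone_in_sample_size(args):
    cap_d, ds, n = args
    freqs = [TokenDocFrequency(f"t{i}", d, cap_d) for i, d in enumerate(ds)]
    assert (
        corpus_capture(freqs, n).overall
        <= corpus_capture(freqs, n + 1).overall + 1e-12
    )


def test_monte_carlo_agrees_with_analytic():
    rng = np.random.default_rng(5)
    cap_d, n_tokens, n = 60, 20, 12
    ds = rng.integers(1, cap_d + 1, size=n_tokens)
    freqs = [TokenDocFrequency(f"t{i}", int(d), cap_d) for i, d in enumerate(ds)]
    analytic = corpus_capture(freqs, n).overall
    reps = 5000
    hits = np.zeros(n_tokens)
    for _ in range(reps):
        sample = set(rng.choice(cap_d, size=n, replace=False).tolist())
        for i, d in enumerate(ds):
            if set(range(int(d))) & sample:
                hits[i] += 1
    mc = float(np.mean(hits / reps))
    se = math.sqrt(analytic * (1 - analytic) / (reps * n_tokens)) + 1e-9
    assert abs(mc - analytic) < max(3 * se, 0.01)


class TestMinSampleSize:
    def test_rare_token_forces_full_census_for_certainty(self):
        freqs = [TokenDocFrequency("rare", 1, 20), TokenDocFrequency("c", 20, 20)]
        assert min_sample_size(freqs, 1.0) == 20

    def test_ubiquitous_tokens_need_one_document(self):
        freqs = [TokenDocFrequency(f"t{i}", 15, 15) for i in range(4)]
        assert min_sample_size(freqs, 0.99) == 1

    def test_binary_search_equals_linear_scan_on_zipf_table(self):
        cap_d = 300
        rng = np.random.default_rng(9)
        ranks = np.arange(1, 41)
        ds = np.maximum(1, (cap_d / ranks ** 1.2).astype(int))
        freqs = [
            TokenDocFrequency(f"t{i}", int(min(d, cap_d)), cap_d)
            for i, d in enumerate(ds)
        ]
        target = 0.9
        fast = min_sample_size(freqs, target)
        linear = next(
            n for n in range(1, cap_d + 1)
            if corpus_capture(freqs, n).overall >= target
        )
        assert fast == linear

    def test_invalid_target_rejected(self):
        with pytest.raises(SizingError):
            min_sample_size([TokenDocFrequency("t", 1, 5)], 0.0)
        with pytest.raises(SizingError):
            min_sample_size([TokenDocFrequency("t", 1, 5)], 1.5)


def test_doc_frequency_table_uses_capture_policy():
    docs = ["basal cell carcinoma 1.2 mm", "no carcinoma here", "nothing"]
    table = doc_frequency_table(docs, ["basal cell carcinoma", "1.2"])
    by_token = {f.token: f.doc_frequency for f in table}
    # "1.2" contributes no capture-policy token; "carcinoma" occurs in 2 docs
    assert by_token == {"basal": 1, "cell": 1, "carcinoma": 2}
    assert all(f.corpus_size == 3 for f in table)
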