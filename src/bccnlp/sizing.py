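"""Token capture-probability estimation for sizing a validation corpus.

For a token occurring in ``d`` of ``D`` reference documents, the
probability that a uniform without-replacement sample of ``N`` documents
contains the token at least once is hypergeometric:

    P(capture) = 1 - C(D - d, N) / C(D, N)

The corpus-level capture probability aggregates per-token probabilities
over a concept vocabulary — by default their mean, alternatively the
fraction of tokens whose individual probability reaches a threshold.  The
smallest sample size achieving a target capture probability is found by
binary search (valid because capture is non-decreasing in ``N``).

The concept vocabulary is drawn from a user-supplied term list using the
``capture`` token policy (alphanumeric sequences beginning with a letter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy.special import gammaln

from .preprocessing import capture_tokens


class SizingError(ValueError):
    pass


@dataclass(frozen=True)
class TokenDocFrequency:
    token: str
    doc_frequency: int
    corpus_size: int

    def __post_init__(self) -> None:
        if not (1 <= self.doc_frequency <= self.corpus_size):
            raise SizingError(
                f"token {self.token!r}: doc frequency {self.doc_frequency} "
                f"outside [1, {self.corpus_size}]"
            )


@dataclass
class CaptureEstimate:
    sample_size: int
    per_token: dict[str, float]
    overall: float
    aggregation: str = "mean"


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def token_capture_probability(freq: TokenDocFrequency, n: int) -> float:
    """P(token appears >= once in a without-replacement sample of ``n`` docs)."""
    d, cap_d = freq.doc_frequency, freq.corpus_size
    if not (0 <= n <= cap_d):
        raise SizingError(f"sample size {n} outside [0, {cap_d}]")
    if n == 0:
        return 0.0
    if n > cap_d - d:
        return 1.0
    log_p_miss = _log_comb(cap_d - d, n) - _log_comb(cap_d, n)
    return float(1.0 - math.exp(log_p_miss))


def corpus_capture(
    frequencies: Iterable[TokenDocFrequency],
    n: int,
    aggregation: str = "mean",
    threshold: float = 0.9,
) -> CaptureEstimate:
    freqs = list(frequencies)
    if not freqs:
        raise SizingError("empty frequency table")
    sizes = {f.corpus_size for f in freqs}
    if len(sizes) != 1:
        raise SizingError(f"inconsistent corpus sizes {sorted(sizes)}")
    per_token = {f.token: token_capture_probability(f, n) for f in freqs}
    if aggregation == "mean":
        overall = sum(per_token.values()) / len(per_token)
    elif aggregation == "fraction":
        overall = sum(1 for p in per_token.values() if p >= threshold) / len(per_token)
    else:
        raise SizingError(f"unknown aggregation {aggregation!r}")
    return CaptureEstimate(n, per_token, overall, aggregation)


def min_sample_size(
    frequencies: Iterable[TokenDocFrequency],
    target: float,
    aggregation: str = "mean",
    threshold: float = 0.9,
) -> int:
    """Smallest N with corpus capture >= target (binary search over N)."""
    if not (0 < target <= 1):
        raise SizingError(f"target {target} outside (0, 1]")
    freqs = list(frequencies)
    if not freqs:
        raise SizingError("empty frequency table")
    cap_d = freqs[0].corpus_size

    def overall(n: int) -> float:
        return corpus_capture(freqs, n, aggregation, threshold).overall

    if overall(cap_d) < target:
        raise SizingError("target capture unreachable even with the full corpus")
    lo, hi = 1, cap_d
    while lo < hi:
        mid = (lo + hi) // 2
        if overall(mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def doc_frequency_table(
    document_texts: Iterable[str], concept_terms: Iterable[str]
) -> list[TokenDocFrequency]:
    """Per-token document frequencies over a reference corpus, restricted to
    the capture-policy tokens of the concept term list.  Concept tokens that
    never occur in the corpus are omitted (their capture probability is
    undefined under the without-replacement model)."""
    vocab: list[str] = []
    seen = set()
    for term in concept_terms:
        for tok in capture_tokens(term):
            if tok not in seen:
                seen.add(tok)
                vocab.append(tok)
    if not vocab:
        raise SizingError("concept term list yields no capture-policy tokens")
    counts = {tok: 0 for tok in vocab}
    n_docs = 0
    for text in document_texts:
        n_docs += 1
        doc_tokens = set(capture_tokens(text))
        for tok in vocab:
            if tok in doc_tokens:
                counts[tok] += 1
    if n_docs == 0:
        raise SizingError("empty reference corpus")
    return [
        TokenDocFrequency(tok, c, n_docs) for tok, c in counts.items() if c > 0
    ]
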