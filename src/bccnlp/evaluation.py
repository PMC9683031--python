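"""Scoring machinery: key/response alignment, strict/average/lenient
precision-recall-F1, corpus aggregation with confidence intervals, token
confusion matrices, Cohen's kappa, positive specific agreement and
pairwise-F1 inter-annotator agreement.

Terminology follows the usual information-extraction conventions: the
*key* set is the reference (gold) annotation, the *response* set is the
system (or second annotator).  Aligned pairs are *correct* when
coextensive and feature-compatible, *partial* when merely overlapping;
unmatched key annotations are *missing* and unmatched response
annotations *spurious*.  Feature compatibility is inclusion: every key
feature must appear in the response with an equal normalised value.

The three match schemes weight partial pairs 0 (strict), 1/2 (average)
or 1 (lenient):

    P = (correct + w * partial) / (correct + spurious + partial)
    R = (correct + w * partial) / (correct + missing  + partial)
    F1 = 2PR / (P + R)

Alignment is an exact lexicographic optimal assignment — maximise the
number of coextensive compatible pairs first, then the number of
overlapping compatible pairs — solved as a linear assignment problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .annotations import Annotation, AnnotationSet, Corpus, Document, coextensive, overlaps
from .preprocessing import tokenize_text
from .textnorm import values_equal

SCHEME_WEIGHTS = {"strict": 0.0, "average": 0.5, "lenient": 1.0}

NONE_LABEL = "NONE"


class EvaluationError(ValueError):
    pass


@dataclass
class EvalCounts:
    correct: int = 0
    partial: int = 0
    missing: int = 0
    spurious: int = 0

    def __post_init__(self) -> None:
        if min(self.correct, self.partial, self.missing, self.spurious) < 0:
            raise EvaluationError("counts must be non-negative")

    @property
    def key_total(self) -> int:
        return self.correct + self.partial + self.missing

    @property
    def response_total(self) -> int:
        return self.correct + self.partial + self.spurious

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(
            self.correct + other.correct,
            self.partial + other.partial,
            self.missing + other.missing,
            self.spurious + other.spurious,
        )


@dataclass(frozen=True)
class ScoreTriple:
    precision: float
    recall: float
    f1: float


def feature_compatible(key: Annotation, response: Annotation) -> bool:
    """Inclusion test: every key feature present in the response with an
    equal normalised value."""
    for name, kv in key.features.items():
        if name not in response.features or not values_equal(kv, response.features[name]):
            return False
    return True


def align(
    key: AnnotationSet | list[Annotation],
    response: AnnotationSet | list[Annotation],
    category: str | None = None,
) -> EvalCounts:
    """Align two annotation sets for one category and tally the outcome.

    The pairing maximises the number of coextensive feature-compatible
    pairs, then the number of overlapping feature-compatible pairs; each
    annotation is used at most once.
    """
    if isinstance(key, AnnotationSet) and isinstance(response, AnnotationSet):
        if key.doc_id is not None and response.doc_id is not None and key.doc_id != response.doc_id:
            raise EvaluationError(
                f"sets reference different documents: {key.doc_id!r} vs {response.doc_id!r}"
            )
    keys = [a for a in key if category is None or a.category == category]
    resps = [a for a in response if category is None or a.category == category]
    nk, nr = len(keys), len(resps)
    if nk == 0 or nr == 0:
        return EvalCounts(missing=nk, spurious=nr)
    big = min(nk, nr) + 1
    weights = np.zeros((nk, nr))
    for i, k in enumerate(keys):
        for j, r in enumerate(resps):
            if k.category != r.category or not overlaps(k.span, r.span):
                continue
            if not feature_compatible(k, r):
                continue
            weights[i, j] = big if coextensive(k.span, r.span) else 1.0
    rows, cols = linear_sum_assignment(weights, maximize=True)
    correct = partial = 0
    for i, j in zip(rows, cols):
        if weights[i, j] >= big:
            correct += 1
        elif weights[i, j] > 0:
            partial += 1
    return EvalCounts(
        correct=correct,
        partial=partial,
        missing=nk - correct - partial,
        spurious=nr - correct - partial,
    )


def align_all(
    key: AnnotationSet, response: AnnotationSet, categories=None
) -> dict[str, EvalCounts]:
    if categories is None:
        categories = sorted(set(key.categories()) | set(response.categories()))
    return {c: align(key, response, c) for c in categories}


def score(counts: EvalCounts, scheme: str = "lenient") -> ScoreTriple:
    """Precision/recall/F1 under a match scheme.

    A zero denominator scores 1 when the other side is also empty (both
    sets agreed that there was nothing to extract) and 0 otherwise.
    """
    w = SCHEME_WEIGHTS[scheme]
    num = counts.correct + w * counts.partial
    p_den = counts.correct + counts.spurious + counts.partial
    r_den = counts.correct + counts.missing + counts.partial
    if p_den == 0:
        precision = 1.0 if r_den == 0 else 0.0
    else:
        precision = num / p_den
    if r_den == 0:
        recall = 1.0 if p_den == 0 else 0.0
    else:
        recall = num / r_den
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return ScoreTriple(precision, recall, f1)


# ---------------------------------------------------------------------------
# Corpus-level evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreWithCI:
    precision: float
    recall: float
    f1: float
    precision_ci: tuple[float, float] = (math.nan, math.nan)
    recall_ci: tuple[float, float] = (math.nan, math.nan)
    f1_ci: tuple[float, float] = (math.nan, math.nan)
    n_documents: int = 0


@dataclass
class CorpusEvaluation:
    scheme: str
    aggregation: str
    overall: ScoreWithCI
    per_category: dict[str, ScoreWithCI] = field(default_factory=dict)
    micro_overall: ScoreTriple | None = None
    warnings: list[str] = field(default_factory=list)


def _mean_ci(values: list[float], rng=None, method: str = "normal") -> tuple[float, tuple[float, float]]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2:
        return mean, (mean, mean)
    if method == "bootstrap":
        rng = rng or np.random.default_rng(0)
        boot = rng.choice(arr, size=(2000, len(arr)), replace=True).mean(axis=1)
        return mean, (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    half = 1.96 * float(arr.std(ddof=1)) / math.sqrt(len(arr))
    return mean, (mean - half, mean + half)


def evaluate_corpus(
    corpus: Corpus,
    key_label: str = "gold",
    response_label: str = "system",
    scheme: str = "lenient",
    aggregation: str = "macro",
    ci_method: str = "normal",
) -> CorpusEvaluation:
    """Score a corpus.

    macro: mean of per-document scores with a normal-approximation 95% CI
    (per-document overall scores pool counts across categories within the
    document); micro: scores computed on counts summed over the corpus.
    Both are reported, ``aggregation`` selecting which fills ``overall``.
    """
    if aggregation not in ("macro", "micro"):
        raise EvaluationError(f"unknown aggregation {aggregation!r}")
    warnings: list[str] = []
    doc_counts: list[dict[str, EvalCounts]] = []
    for doc in corpus:
        try:
            key = doc.annset(key_label, create=False)
            resp = doc.annset(response_label, create=False)
        except KeyError as exc:
            warnings.append(str(exc))
            continue
        doc_counts.append(align_all(key, resp))

    categories = sorted({c for dc in doc_counts for c in dc})
    totals = {c: EvalCounts() for c in categories}
    for dc in doc_counts:
        for c, counts in dc.items():
            totals[c] = totals[c] + counts

    per_category: dict[str, ScoreWithCI] = {}
    for c in categories:
        if aggregation == "micro":
            s = score(totals[c], scheme)
            per_category[c] = ScoreWithCI(s.precision, s.recall, s.f1)
            continue
        docs_scores = [
            score(dc[c], scheme)
            for dc in doc_counts
            if c in dc and (dc[c].key_total > 0 or dc[c].response_total > 0)
        ]
        if not docs_scores:
            continue
        p, pci = _mean_ci([s.precision for s in docs_scores], method=ci_method)
        r, rci = _mean_ci([s.recall for s in docs_scores], method=ci_method)
        f, fci = _mean_ci([s.f1 for s in docs_scores], method=ci_method)
        per_category[c] = ScoreWithCI(p, r, f, pci, rci, fci, len(docs_scores))

    grand = EvalCounts()
    for c in categories:
        grand = grand + totals[c]
    micro_overall = score(grand, scheme)

    if aggregation == "micro":
        overall = ScoreWithCI(
            micro_overall.precision, micro_overall.recall, micro_overall.f1,
            n_documents=len(doc_counts),
        )
    else:
        doc_overall = []
        for dc in doc_counts:
            pooled = EvalCounts()
            for counts in dc.values():
                pooled = pooled + counts
            doc_overall.append(score(pooled, scheme))
        p, pci = _mean_ci([s.precision for s in doc_overall], method=ci_method)
        r, rci = _mean_ci([s.recall for s in doc_overall], method=ci_method)
        f, fci = _mean_ci([s.f1 for s in doc_overall], method=ci_method)
        overall = ScoreWithCI(p, r, f, pci, rci, fci, len(doc_overall))

    return CorpusEvaluation(
        scheme=scheme,
        aggregation=aggregation,
        overall=overall,
        per_category=per_category,
        micro_overall=micro_overall,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Token-level agreement
# ---------------------------------------------------------------------------

@dataclass
class TokenLabelTable:
    """One label per token for one annotator, with a NONE label for
    unannotated tokens.  Ties (a token under two annotations) resolve in
    favour of the longest annotation, then the schema-earlier category."""

    doc_id: str
    tokens: list[tuple[int, int]]
    labels: list[str]


def build_token_table(
    doc: Document,
    set_name: str,
    category_order: list[str] | None = None,
    policy: str = "general",
) -> TokenLabelTable:
    aset = doc.annset(set_name, create=False)
    tokens = [(s, e) for s, e, _ in tokenize_text(doc.text, policy)]
    anns = sorted(aset, key=Annotation.sort_key)

    def rank(cat: str) -> int:
        if category_order and cat in category_order:
            return category_order.index(cat)
        return len(category_order or []) + 1

    labels = []
    for s, e in tokens:
        covering = [a for a in anns if a.start <= s and e <= a.end]
        if not covering:
            labels.append(NONE_LABEL)
        else:
            best = min(covering, key=lambda a: (-(a.end - a.start), rank(a.category), a.category))
            labels.append(best.category)
    return TokenLabelTable(doc.id, tokens, labels)


def token_confusion(a: TokenLabelTable, b: TokenLabelTable) -> pd.DataFrame:
    """Square confusion matrix over categories plus NONE; cell (i, j) counts
    tokens labelled i by the first annotator and j by the second."""
    if a.tokens != b.tokens:
        raise EvaluationError("token universes differ between the two tables")
    cats = sorted(set(a.labels) | set(b.labels) - {NONE_LABEL})
    cats = [c for c in cats if c != NONE_LABEL] + [NONE_LABEL]
    mat = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    for la, lb in zip(a.labels, b.labels):
        mat.loc[la, lb] += 1
    return mat


def cohen_kappa(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cohen's kappa from a square confusion matrix."""
    m = np.asarray(matrix, dtype=float)
    n = m.sum()
    if n <= 0:
        raise EvaluationError("confusion matrix is empty")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / (n * n)
    if pe >= 1.0:
        return 1.0 if po >= 1.0 else 0.0
    return (po - pe) / (1 - pe)


def specific_agreement(matrix: pd.DataFrame, category: str) -> float:
    """Positive specific agreement for one category:
    2 * both / (first-annotator total + second-annotator total); 0/0 -> 1."""
    if category not in matrix.index:
        raise EvaluationError(f"category {category!r} not in matrix")
    both = float(matrix.loc[category, category])
    denom = float(matrix.loc[category].sum() + matrix[category].sum())
    if denom == 0:
        return 1.0
    return 2.0 * both / denom


@dataclass
class PairwiseF1:
    f1: float
    swapped_f1: float
    per_category: dict[str, float]


def pairwise_f1(
    a: AnnotationSet, b: AnnotationSet, scheme: str = "lenient", categories=None
) -> PairwiseF1:
    """F1 treating ``a`` as key and ``b`` as response, with the role-swapped
    value reported as a symmetry check (equal under every scheme, since the
    swap exchanges missing and spurious)."""
    counts = align_all(a, b, categories)
    pooled = EvalCounts()
    for c in counts.values():
        pooled = pooled + c
    fwd = score(pooled, scheme).f1
    swapped = EvalCounts(pooled.correct, pooled.partial, pooled.spurious, pooled.missing)
    return PairwiseF1(
        f1=fwd,
        swapped_f1=score(swapped, scheme).f1,
        per_category={c: score(cc, scheme).f1 for c, cc in counts.items()},
    )


def iaa_report(
    corpus: Corpus,
    a_label: str,
    b_label: str,
    gold_label: str | None = None,
    scheme: str = "lenient",
    category_order: list[str] | None = None,
) -> dict:
    """Inter-annotator agreement summary: Cohen's kappa on annotated tokens,
    per-category positive specific agreement, pairwise F1, and (when a gold
    set is given) the per-category difference between each annotator's F1
    against gold."""
    mats = []
    pooled_a = EvalCounts()
    per_cat_counts: dict[str, EvalCounts] = {}
    diff_counts_a: dict[str, EvalCounts] = {}
    diff_counts_b: dict[str, EvalCounts] = {}
    for doc in corpus:
        ta = build_token_table(doc, a_label, category_order)
        tb = build_token_table(doc, b_label, category_order)
        mats.append(token_confusion(ta, tb))
        for c, counts in align_all(
            doc.annset(a_label, create=False), doc.annset(b_label, create=False)
        ).items():
            per_cat_counts[c] = per_cat_counts.get(c, EvalCounts()) + counts
            pooled_a = pooled_a + counts
        if gold_label:
            gold = doc.annset(gold_label, create=False)
            for c, counts in align_all(gold, doc.annset(a_label, create=False)).items():
                diff_counts_a[c] = diff_counts_a.get(c, EvalCounts()) + counts
            for c, counts in align_all(gold, doc.annset(b_label, create=False)).items():
                diff_counts_b[c] = diff_counts_b.get(c, EvalCounts()) + counts

    cats = sorted({c for m in mats for c in m.index if c != NONE_LABEL})
    matrix = pd.DataFrame(0, index=cats + [NONE_LABEL], columns=cats + [NONE_LABEL], dtype=int)
    for m in mats:
        matrix = matrix.add(m, fill_value=0).astype(int)

    # kappa on annotated tokens: drop tokens neither annotator labelled
    reduced = matrix.copy()
    reduced.loc[NONE_LABEL, NONE_LABEL] = 0
    report = {
        "kappa_annotated_tokens": cohen_kappa(reduced),
        "kappa_all_tokens": cohen_kappa(matrix),
        "specific_agreement": {c: specific_agreement(matrix, c) for c in cats},
        "pairwise_f1": score(pooled_a, scheme).f1,
        "per_category_f1": {
            c: score(cc, scheme).f1 for c, cc in sorted(per_cat_counts.items())
        },
        "confusion_matrix": matrix,
    }
    if gold_label:
        diffs = {}
        for c in sorted(set(diff_counts_a) | set(diff_counts_b)):
            fa = score(diff_counts_a.get(c, EvalCounts()), scheme).f1
            fb = score(diff_counts_b.get(c, EvalCounts()), scheme).f1
            diffs[c] = abs(fa - fb)
        report["f1_difference_vs_gold"] = diffs
    return report
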