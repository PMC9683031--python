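"""Alignment, scoring schemes, corpus aggregation and agreement statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bccnlp.annotations import Document, Span, overlaps, coextensive
from bccnlp.evaluation import (
    EvalCounts,
    EvaluationError,
    align,
    build_token_table,
    cohen_kappa,
    evaluate_corpus,
    feature_compatible,
    pairwise_f1,
    score,
    specific_agreement,
    token_confusion,
)
from fixture_counts import COUNTS

counts_strategy = st.builds(
    EvalCounts,
    correct=st.integers(0, 30),
    partial=st.integers(0, 30),
    missing=st.integers(0, 30),
    spurious=st.integers(0, 30),
)


def _sets(key_specs, resp_specs, text_len=60):
    doc = Document("d", "x" * text_len)
    k, r = doc.annset("key"), doc.annset("resp")
    for start, end, feats in key_specs:
        k.add("E", start, end, feats)
    for start, end, feats in resp_specs:
        r.add("E", start, end, feats)
    return k, r


class TestAlign:
    def test_key_features_must_be_included_in_response(self):
        k, r = _sets([(0, 10, {"site": "ear"})], [(0, 10, {"site": "ear", "extra": "x"})])
        assert align(k, r, "E") == EvalCounts(correct=1)

    def test_overlap_without_coextension_is_partial(self):
        k, r = _sets([(0, 10, {})], [(3, 12, {})])
        assert align(k, r, "E") == EvalCounts(partial=1)

    def test_feature_clash_yields_missing_and_spurious(self):
        k, r = _sets([(0, 10, {"site": "ear"})], [(0, 10, {"site": "nose"})])
        assert align(k, r, "E") == EvalCounts(missing=1, spurious=1)

    def test_sets_from_different_documents_rejected(self):
        d1, d2 = Document("a", "xxxx"), Document("b", "xxxx")
        d1.annset("key").add("E", 0, 1)
        d2.annset("resp").add("E", 0, 1)
        with pytest.raises(EvaluationError):
            align(d1.annset("key"), d2.annset("resp"), "E")

    def test_each_annotation_used_at_most_once(self):
        k, r = _sets([(0, 10, {}), (0, 10, {})], [(0, 10, {})])
        assert align(k, r, "E") == EvalCounts(correct=1, missing=1)

    def test_assignment_finds_pairing_greedy_longest_overlap_would_miss(self):
        # K1=[0,5) overlaps only R1=[4,6); K2=[4,8) overlaps R1 (longer) and
        # R2=[7,8).  Pairing K2 with R1 strands K1; the optimal assignment
        # matches both keys.
        k, r = _sets([(0, 5, {}), (4, 8, {})], [(4, 6, {}), (7, 8, {})])
        assert align(k, r, "E") == EvalCounts(partial=2)

    def test_coextensive_matches_preferred_over_more_partials(self):
        # two coextensive keys, one compatible response pairing each way
        k, r = _sets(
            [(0, 5, {"f": "a"}), (0, 5, {})],
            [(0, 5, {"f": "a"}), (3, 8, {})],
        )
        out = align(k, r, "E")
        assert out.correct >= 1 and out.correct + out.partial == 2


def _brute_force(keys, resps):
    """Exhaustive lexicographic-optimal assignment for small sets."""
    nk, nr = len(keys), len(resps)
    best = (-1, -1)
    indices = list(range(nr)) + [None] * nk
    for perm in set(itertools.permutations(indices, nk)):
        used = [j for j in perm if j is not None]
        if len(used) != len(set(used)):
            continue
        c = p = 0
        ok = True
        for i, j in enumerate(perm):
            if j is None:
                continue
            kk, rr = keys[i], resps[j]
            if not overlaps(kk.span, rr.span) or not feature_compatible(kk, rr):
                ok = False
                break
            if coextensive(kk.span, rr.span):
                c += 1
            else:
                p += 1
        if ok and (c, p) > best:
            best = (c, p)
    return best


def test_align_agrees_with_exhaustive_assignment_on_random_documents():
    rng = np.random.default_rng(42)
    feature_pool = [{}, {"f": "a"}, {"f": "b"}, {"f": "a", "g": "c"}]
    for _ in range(150):
        nk, nr = int(rng.integers(0, 5)), int(rng.integers(0, 5))
        mk = [
            (int(s), int(s + rng.integers(1, 8)), feature_pool[int(rng.integers(4))])
            for s in rng.integers(0, 20, size=nk)
        ]
        mr = [
            (int(s), int(s + rng.integers(1, 8)), feature_pool[int(rng.integers(4))])
            for s in rng.integers(0, 20, size=nr)
        ]
        k, r = _sets(mk, mr)
        got = align(k, r, "E")
        want_c, want_p = _brute_force(list(k), list(r))
        if want_c < 0:
            want_c, want_p = 0, 0
        assert (got.correct, got.partial) == (want_c, want_p), (mk, mr)


class TestScore:
    def test_lenient_on_published_clinical_details_counts(self):
        # (49 correct, 7 missing, 4 spurious, 33 partial): lenient P = 82/86
        counts = EvalCounts(correct=49, missing=7, spurious=4, partial=33)
        s = score(counts, "lenient")
        assert s.precision == pytest.approx(82 / 86)
        assert s.recall == pytest.approx(82 / 89)

    def test_average_applies_half_partial_weight(self):
        counts = EvalCounts(correct=49, missing=7, spurious=4, partial=33)
        s = score(counts, "average")
        assert s.precision == pytest.approx(65.5 / 86)

    def test_all_partial_scores_perfect_under_lenient(self):
        counts = EvalCounts(partial=38)
        s = score(counts, "lenient")
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_empty_vs_empty_scores_one(self):
        s = score(EvalCounts(), "strict")
        assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)

    def test_empty_response_against_nonempty_key_scores_zero(self):
        s = score(EvalCounts(missing=5), "lenient")
        assert (s.precision, s.recall, s.f1) == (0.0, 0.0, 0.0)

    @settings(max_examples=300, derandomize=True)
    @given(counts_strategy)
    def test_scheme_ordering_strict_average_lenient(self, counts):
        s, a, l = (score(counts, x) for x in ("strict", "average", "lenient"))
        assert s.precision <= a.precision <= l.precision
        assert s.recall <= a.recall <= l.recall
        assert s.f1 <= a.f1 <= l.f1

    @settings(max_examples=300, derandomize=True)
    @given(counts_strategy, st.sampled_from(["strict", "average", "lenient"]))
    def test_f1_between_min_and_max_of_p_and_r(self, counts, scheme):
        s = score(counts, scheme)
        assert min(s.precision, s.recall) - 1e-12 <= s.f1
        assert s.f1 <= max(s.precision, s.recall) + 1e-12


def test_count_identities_on_align_output():
    rng = np.random.default_rng(1)
    for _ in range(30):
        mk = [(int(s), int(s) + int(rng.integers(1, 6)), {}) for s in rng.integers(0, 30, 4)]
        mr = [(int(s), int(s) + int(rng.integers(1, 6)), {}) for s in rng.integers(0, 30, 3)]
        k, r = _sets(mk, mr)
        c = align(k, r, "E")
        assert c.key_total == len(mk)
        assert c.response_total == len(mr)


class TestCorpusEvaluation:
    def _corpus(self, docs):
        from bccnlp.annotations import Corpus

        corpus = Corpus()
        for i, (key_specs, resp_specs) in enumerate(docs):
            d = Document(f"d{i}", "x" * 40)
            for s, e, f in key_specs:
                d.annset("gold").add("E", s, e, f)
            for s, e, f in resp_specs:
                d.annset("system").add("E", s, e, f)
            corpus.add(d)
        return corpus

    def test_single_document_macro_equals_micro(self):
        corpus = self._corpus([([(0, 5, {})], [(0, 5, {})])])
        macro = evaluate_corpus(corpus, aggregation="macro")
        micro = evaluate_corpus(corpus, aggregation="micro")
        assert macro.overall.f1 == micro.overall.f1 == 1.0

    def test_two_documents_at_one_and_zero_average_to_half(self):
        corpus = self._corpus(
            [([(0, 5, {})], [(0, 5, {})]), ([(0, 5, {})], [(20, 25, {})])]
        )
        ev = evaluate_corpus(corpus, aggregation="macro")
        assert ev.overall.precision == pytest.approx(0.5)

    def test_perfect_corpus_has_zero_width_ci(self):
        corpus = self._corpus([([(0, 5, {})], [(0, 5, {})])] * 4)
        ev = evaluate_corpus(corpus, aggregation="macro")
        assert ev.overall.f1 == 1.0
        assert ev.overall.f1_ci == (1.0, 1.0)

    def test_missing_set_warns_and_continues(self):
        from bccnlp.annotations import Corpus

        corpus = Corpus()
        good = Document("good", "xxxx")
        good.annset("gold").add("E", 0, 2)
        good.annset("system").add("E", 0, 2)
        corpus.add(good)
        corpus.add(Document("bad", "xxxx"))  # no sets at all
        ev = evaluate_corpus(corpus)
        assert len(ev.warnings) == 1
        assert ev.overall.f1 == 1.0


class TestTokenAgreement:
    def _tables(self, text, a_spans, b_spans):
        doc = Document("d", text)
        doc.annset("A"), doc.annset("B")
        for s, e, cat in a_spans:
            doc.annset("A").add(cat, s, e)
        for s, e, cat in b_spans:
            doc.annset("B").add(cat, s, e)
        return (
            build_token_table(doc, "A"),
            build_token_table(doc, "B"),
        )

    def test_identical_tables_give_diagonal_matrix(self):
        ta, tb = self._tables("one two three", [(0, 3, "X")], [(0, 3, "X")])
        m = token_confusion(ta, tb)
        assert m.loc["X", "X"] == 1
        assert m.values.sum() == m.values.trace()

    def test_tokens_seen_by_one_annotator_only(self):
        ta, tb = self._tables("alpha beta gamma delta epsilon", [(0, 16, "X")], [])
        m = token_confusion(ta, tb)
        assert m.loc["X", "NONE"] == 3

    def test_row_sums_conserve_first_annotator_labels(self):
        ta, tb = self._tables(
            "a b c d e", [(0, 3, "X"), (4, 7, "Y")], [(0, 1, "X"), (4, 9, "Y")]
        )
        m = token_confusion(ta, tb)
        from collections import Counter

        assert dict(m.sum(axis=1)) == dict(Counter(ta.labels))

    def test_differing_token_universes_rejected(self):
        d1, d2 = Document("d", "one two"), Document("d", "one two three")
        d1.annset("A")
        d2.annset("B")
        with pytest.raises(EvaluationError):
            token_confusion(build_token_table(d1, "A"), build_token_table(d2, "B"))

    def test_longest_annotation_wins_token_label_ties(self):
        doc = Document("d", "perineural invasion seen")
        doc.annset("A").add("Long", 0, 19)
        doc.annset("A").add("Short", 0, 10)
        table = build_token_table(doc, "A")
        assert table.labels[0] == "Long"


class TestKappaAndAgreement:
    def test_perfect_diagonal_gives_kappa_one(self):
        assert cohen_kappa(np.diag([5, 7, 3])) == 1.0

    def test_worked_two_by_two_matrix(self):
        # po = 0.7, pe = 0.5 -> kappa = 0.4 (hand-checked by counting pairs)
        assert cohen_kappa(np.array([[20, 5], [10, 15]])) == pytest.approx(0.4)

    def test_independent_labels_give_kappa_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, size=20000)
        b = rng.integers(0, 2, size=20000)
        m = np.zeros((2, 2))
        for x, y in zip(a, b):
            m[x, y] += 1
        se = 1 / np.sqrt(20000)
        assert abs(cohen_kappa(m)) < 3 * se

    def test_degenerate_chance_agreement(self):
        assert cohen_kappa(np.array([[10, 0], [0, 0]])) == 1.0

    def test_specific_agreement_examples(self):
        m = pd.DataFrame(
            [[8, 2, 0], [2, 0, 0], [0, 0, 5]],
            index=["X", "Y", "NONE"],
            columns=["X", "Y", "NONE"],
        )
        assert specific_agreement(m, "X") == pytest.approx(16 / 20)
        assert specific_agreement(m, "Y") == 0.0

    def test_specific_agreement_empty_category_is_one(self):
        m = pd.DataFrame([[0, 0], [0, 9]], index=["X", "NONE"], columns=["X", "NONE"])
        assert specific_agreement(m, "X") == 1.0


class TestPairwiseF1:
    def test_identical_sets_score_one(self):
        k, r = _sets([(0, 5, {})], [(0, 5, {})])
        assert pairwise_f1(k, r).f1 == 1.0

    def test_disjoint_sets_score_zero(self):
        k, r = _sets([(0, 5, {})], [(20, 25, {})])
        assert pairwise_f1(k, r).f1 == 0.0

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 8)), max_size=5),
           st.lists(st.tuples(st.integers(0, 40), st.integers(1, 8)), max_size=5),
           st.sampled_from(["strict", "average", "lenient"]))
    def test_f1_symmetric_under_role_swap(self, a_spans, b_spans, scheme):
        k, r = _sets(
            [(s, s + l, {}) for s, l in a_spans],
            [(s, s + l, {}) for s, l in b_spans],
        )
        fwd = pairwise_f1(k, r, scheme)
        rev = pairwise_f1(r, k, scheme)
        assert fwd.f1 == pytest.approx(rev.f1)
        assert fwd.f1 == pytest.approx(fwd.swapped_f1)


def test_published_count_table_reproduces_perfect_lenient_cells():
    from fixture_counts import COUNTS, PERFECT_ENTITIES

    for corpus_name in ("training", "validation"):
        for entity in PERFECT_ENTITIES:
            _, _, match, missing, spurious, partial = COUNTS[corpus_name][entity]
            s = score(
                EvalCounts(match, partial, missing, spurious), "lenient"
            )
            assert (s.precision, s.recall, s.f1) == (1.0, 1.0, 1.0)
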