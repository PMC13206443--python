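"""Query classification, BM25/dense scoring oracles, and hybrid retrieval."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mealrank.corpus import RecipeCorpus
from mealrank.retrieval import (
    AlphaPolicy, DenseIndex, HashedEmbedder, QueryClass, SparseIndex,
    classify_query, compute_alpha, hybrid_retrieve, minmax_normalize, tokenize,
)

from conftest import make_recipe


class TestClassifier:
    @pytest.mark.parametrize("q,expected", [
        ("chicken, rice, broccoli", QueryClass.INGREDIENT_LIST),
        ("pizza", QueryClass.DISH_NAME),
        ("Immune boosting dinner", QueryClass.INTENT_MARKER),
        ("what should I cook tonight", QueryClass.DEFAULT),
        ("salmon, spinach", QueryClass.INGREDIENT_LIST),
        ("chicken curry", QueryClass.DISH_NAME),
        ("healthy pizza", QueryClass.INTENT_MARKER),  # intent outranks dish
    ])
    def test_query_classes(self, q, expected):
        assert classify_query(q) == expected

    @pytest.mark.parametrize("q,alpha", [
        ("Immune boosting dinner", 0.65),
        ("pizza", 0.20),
        ("chicken, rice, broccoli", 0.35),
        ("what should I cook tonight", 0.50),
    ])
    def test_alpha_values(self, q, alpha):
        assert compute_alpha(q) == alpha

    def test_alpha_always_in_default_table(self):
        queries = ["soup", "a very long and winding request", "beef, lentil",
                   "post workout meal", "quinoa"]
        for q in queries:
            assert compute_alpha(q) in {0.35, 0.20, 0.65, 0.50}

    def test_alpha_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            AlphaPolicy({QueryClass.DEFAULT: 1.2})


@pytest.fixture(scope="module")
def corpus():
    return RecipeCorpus([
        make_recipe("d1", title="chicken soup", ingredients=("chicken", "carrot")),
        make_recipe("d2", title="chicken chicken pie", ingredients=("chicken", "butter")),
        make_recipe("d3", title="lentil stew", ingredients=("lentil", "onion")),
    ])


class TestBM25:

    def test_absent_term_scores_zero(self, corpus):
        idx = SparseIndex(corpus)
        assert idx.score("mango", "d1") == 0.0

    def test_present_term_scores_positive(self):
        c = RecipeCorpus([make_recipe("solo", title="plain rice",
                                      ingredients=("rice",))])
        assert SparseIndex(c).score("rice", "solo") > 0.0

    def test_matches_hand_evaluated_okapi_formula(self, corpus):
        """Independent evaluation of the Okapi formula with k1=1.5, b=0.75."""
        idx = SparseIndex(corpus, k1=1.5, b=0.75)
        docs = {r.id: tokenize(r.text) for r in corpus}
        n = len(docs)
        avgdl = sum(len(d) for d in docs.values()) / n
        for q in ("chicken", "chicken soup", "lentil onion stew"):
            terms = q.split()
            for rid, toks in docs.items():
                expected = 0.0
                for t in terms:
                    f = toks.count(t)
                    if f == 0:
                        continue
                    df = sum(1 for d in docs.values() if t in d)
                    idf = math.log(1 + (n - df + 0.5) / (df + 0.5))
                    expected += idf * f * 2.5 / (f + 1.5 * (0.25 + 0.75 * len(toks) / avgdl))
                assert idx.score(q, rid) == pytest.approx(expected)

    def test_repeated_term_scores_higher(self, corpus):
        idx = SparseIndex(corpus)
        assert idx.score("chicken", "d2") > idx.score("chicken", "d1")

    def test_unindexed_recipe_raises(self, corpus):
        with pytest.raises(KeyError):
            SparseIndex(corpus).score("chicken", "nope")


class TestDense:
    def test_identical_text_self_similarity_one(self, small_corpus):
        idx = DenseIndex(small_corpus)
        r = small_corpus["a01"]
        assert idx.score(r.text, "a01") == pytest.approx(1.0)

    def test_disjoint_vocabulary_orthogonal(self):
        c = RecipeCorpus([make_recipe("x", title="zzzz", ingredients=("qqqq",),
                                      steps=())])
        idx = DenseIndex(c)
        assert idx.score("wwww mmmm", "x") == pytest.approx(0.0)

    def test_equals_bruteforce_dot_product(self, small_corpus):
        emb = HashedEmbedder()
        idx = DenseIndex(small_corpus, embedder=emb)
        for q in ("garlic chicken", "salmon dinner", "sweet bars"):
            qv = emb.embed(q)
            for r in small_corpus:
                assert idx.score(q, r.id) == pytest.approx(float(qv @ emb.embed(r.text)))

    def test_embeddings_unit_norm_and_deterministic(self):
        emb = HashedEmbedder()
        v1, v2 = emb.embed("chicken soup"), emb.embed("chicken soup")
        assert np.allclose(v1, v2)
        assert np.linalg.norm(v1) == pytest.approx(1.0)


def _bruteforce_hybrid(q, corpus, sparse, dense, alpha):
    raw_s = {r.id: sparse.score(q, r.id) for r in corpus}
    raw_d = {r.id: dense.score(q, r.id) for r in corpus}
    ns, nd = minmax_normalize(raw_s), minmax_normalize(raw_d)
    scored = [(alpha * nd[i] + (1 - alpha) * ns[i], i) for i in raw_s]
    return [i for s, i in sorted(scored, key=lambda t: (-t[0], t[1]))]


class TestHybrid:
    def test_alpha_one_matches_dense_ordering(self, gen_corpus, gen_indexes):
        sparse, dense = gen_indexes
        q = "garlic chicken dinner"
        got = [c.recipe_id for c in hybrid_retrieve(q, sparse, dense, k=20, alpha=1.0)]
        nd = minmax_normalize(dense.scores(q))
        expect = [i for i in sorted(nd, key=lambda i: (-nd[i], i))][:20]
        assert got == expect

    def test_alpha_zero_matches_sparse_ordering(self, gen_corpus, gen_indexes):
        sparse, dense = gen_indexes
        q = "garlic chicken dinner"
        got = [c.recipe_id for c in hybrid_retrieve(q, sparse, dense, k=20, alpha=0.0)]
        ns = minmax_normalize(sparse.scores(q))
        expect = [i for i in sorted(ns, key=lambda i: (-ns[i], i))][:20]
        assert got == expect

    def test_matches_bruteforce_on_fixture(self, gen_corpus, gen_indexes):
        sparse, dense = gen_indexes
        for q in ("spicy chili skillet", "turmeric salmon", "quick lunch"):
            got = [c.recipe_id for c in hybrid_retrieve(q, sparse, dense, k=len(gen_corpus),
                                                        alpha=0.5)]
            assert got == _bruteforce_hybrid(q, gen_corpus, sparse, dense, 0.5)

    def test_scores_in_unit_interval_and_sorted(self, gen_indexes):
        sparse, dense = gen_indexes
        out = hybrid_retrieve("hearty beef stew", sparse, dense, k=50)
        hs = [c.s_hybrid for c in out]
        assert all(0.0 <= s <= 1.0 for s in hs)
        assert hs == sorted(hs, reverse=True)

    def test_repeated_calls_identical(self, gen_indexes):
        sparse, dense = gen_indexes
        a = [c.recipe_id for c in hybrid_retrieve("salmon rice", sparse, dense, k=30)]
        b = [c.recipe_id for c in hybrid_retrieve("salmon rice", sparse, dense, k=30)]
        assert a == b

    @settings(max_examples=25, deadline=None)
    @given(a=st.floats(0, 1), sv=st.floats(0, 1), dv=st.floats(0, 1),
           delta=st.floats(0.001, 0.5))
    def test_hybrid_monotone_in_each_component(self, a, sv, dv, delta):
        base = a * dv + (1 - a) * sv
        assert a * min(dv + delta, 1.5) + (1 - a) * sv >= base
        assert a * dv + (1 - a) * min(sv + delta, 1.5) >= base
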