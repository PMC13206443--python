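"""Hybrid sparse-dense retrieval with query-adaptive mixing.

The hybrid score is a convex combination

    s_hybrid(q, r) = alpha(q) * s_dense(q, r) + (1 - alpha(q)) * s_bm25(q, r)

where alpha depends on the *shape* of the query: ingredient lists reward
lexical precision (low alpha), short dish names even more so, while fuzzy
intent-laden queries lean on the dense signal (high alpha).  Both component
scores are min-max normalized over the pooled candidates before mixing,
since raw BM25 is unbounded while cosine similarity lives in [-1, 1].

The default dense embedder is a deterministic hashed bag of word and
character-trigram features (no model weights); any encoder with an
``embed(text) -> unit vector`` method can be substituted.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .corpus import Recipe, RecipeCorpus
from .intent import ConfigurationError, IntentLexicon, default_lexicon
from .lexicons import DISH_NAMES, INGREDIENTS

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


class QueryClass(str, Enum):
    INGREDIENT_LIST = "ingredient_list"
    DISH_NAME = "dish_name"
    INTENT_MARKER = "intent_marker"
    DEFAULT = "default"


@dataclass(frozen=True)
class AlphaPolicy:
    """Query-class -> dense-weight alpha table."""

    table: dict[QueryClass, float] = field(default_factory=lambda: {
        QueryClass.INGREDIENT_LIST: 0.35,
        QueryClass.DISH_NAME: 0.20,
        QueryClass.INTENT_MARKER: 0.65,
        QueryClass.DEFAULT: 0.50,
    })

    def __post_init__(self):
        for cls_, a in self.table.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError(f"alpha for {cls_} outside [0, 1]: {a}")

    def __getitem__(self, cls_: QueryClass) -> float:
        return self.table[cls_]


_FOOD_TOKENS = frozenset(
    tok for name in INGREDIENTS for tok in name.split()
) | frozenset(INGREDIENTS)


def _is_food_phrase(seg: str) -> bool:
    toks = tokenize(seg)
    return bool(toks) and all(t in _FOOD_TOKENS for t in toks)


def classify_query(q: str, lexicon: Optional[IntentLexicon] = None) -> QueryClass:
    """Rule-based query-shape classifier, applied in priority order:

    1. ingredient_list — two or more comma-separated food phrases;
    2. intent_marker — the query contains a lexicon intent/health phrase;
    3. dish_name — at most two tokens, all dish or food words;
    4. default.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    segments = [s for s in q.split(",") if s.strip()]
    if len(segments) >= 2 and sum(_is_food_phrase(s) for s in segments) >= 2:
        return QueryClass.INGREDIENT_LIST
    if lexicon.intent_hits(q):
        return QueryClass.INTENT_MARKER
    toks = tokenize(q)
    if 1 <= len(toks) <= 2 and all(
        t in DISH_NAMES or t in _FOOD_TOKENS or " ".join(toks) in DISH_NAMES for t in toks
    ):
        return QueryClass.DISH_NAME
    return QueryClass.DEFAULT


def compute_alpha(
    q: str, policy: Optional[AlphaPolicy] = None, lexicon: Optional[IntentLexicon] = None
) -> float:
    policy = policy if policy is not None else AlphaPolicy()
    return policy[classify_query(q, lexicon)]


# ---------------------------------------------------------------------------
# sparse index (Okapi BM25)
# ---------------------------------------------------------------------------

class SparseIndex:
    """Okapi BM25 index.

    IDF uses the non-negative smoothing ln(1 + (N - df + 0.5)/(df + 0.5)),
    so scores are always >= 0 and exactly 0 when no query term occurs in the
    document.
    """

    def __init__(self, corpus: RecipeCorpus, k1: float = 1.5, b: float = 0.75):
        if k1 <= 0 or not 0.0 <= b <= 1.0:
            raise ConfigurationError(f"invalid BM25 parameters k1={k1}, b={b}")
        self.k1, self.b = k1, b
        self._ids: list[str] = []
        self._tf: dict[str, dict[str, int]] = {}
        self._doclen: dict[str, int] = {}
        self._df: dict[str, int] = {}
        for r in corpus:
            toks = tokenize(r.text)
            tf: dict[str, int] = {}
            for t in toks:
                tf[t] = tf.get(t, 0) + 1
            self._ids.append(r.id)
            self._tf[r.id] = tf
            self._doclen[r.id] = len(toks)
            for t in tf:
                self._df[t] = self._df.get(t, 0) + 1
        self.n_docs = len(self._ids)
        self.avgdl = (sum(self._doclen.values()) / self.n_docs) if self.n_docs else 0.0

    def idf(self, term: str) -> float:
        df = self._df.get(term, 0)
        return math.log(1.0 + (self.n_docs - df + 0.5) / (df + 0.5))

    def score(self, q: str, recipe_id: str) -> float:
        if recipe_id not in self._tf:
            raise KeyError(f"recipe {recipe_id!r} not indexed")
        tf = self._tf[recipe_id]
        dl = self._doclen[recipe_id]
        s = 0.0
        for term in tokenize(q):
            f = tf.get(term, 0)
            if f == 0:
                continue
            denom = f + self.k1 * (1.0 - self.b + self.b * dl / self.avgdl)
            s += self.idf(term) * f * (self.k1 + 1.0) / denom
        return s

    def scores(self, q: str) -> dict[str, float]:
        return {rid: self.score(q, rid) for rid in self._ids}


def bm25_score(index: SparseIndex, q: str, recipe_id: str) -> float:
    return index.score(q, recipe_id)


# ---------------------------------------------------------------------------
# dense index (deterministic hashed embedder by default)
# ---------------------------------------------------------------------------

class HashedEmbedder:
    """L2-normalized hashed bag of word and character-trigram features.

    Feature buckets come from a keyed blake2b digest, so vectors are stable
    across processes and platforms.  Purely lexical: it captures token and
    sub-word overlap, not distributional semantics.
    """

    def __init__(self, dim: int = 256, seed: int = 17):
        self.dim = dim
        self._key = seed.to_bytes(8, "little")

    def _bucket(self, feature: str) -> tuple[int, float]:
        h = hashlib.blake2b(feature.encode(), key=self._key, digest_size=8).digest()
        val = int.from_bytes(h, "little")
        return val % self.dim, 1.0 if (val >> 62) & 1 else -1.0

    def embed(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        for tok in tokenize(text):
            feats = [f"w:{tok}"]
            padded = f"^{tok}$"
            feats += [f"t:{padded[i:i + 3]}" for i in range(len(padded) - 2)]
            for f in feats:
                idx, sign = self._bucket(f)
                v[idx] += sign
        n = np.linalg.norm(v)
        return v / n if n > 0 else v


class DenseIndex:
    def __init__(self, corpus: RecipeCorpus, embedder=None):
        self.embedder = embedder if embedder is not None else HashedEmbedder()
        self._ids = corpus.ids()
        self._vecs = {r.id: self.embedder.embed(r.text) for r in corpus}

    def score(self, q: str, recipe_id: str) -> float:
        if recipe_id not in self._vecs:
            raise KeyError(f"recipe {recipe_id!r} not indexed")
        qv = self.embedder.embed(q)
        rv = self._vecs[recipe_id]
        if qv.shape != rv.shape:
            raise ConfigurationError("query/recipe embedding dimension mismatch")
        return float(qv @ rv)

    def scores(self, q: str) -> dict[str, float]:
        qv = self.embedder.embed(q)
        return {rid: float(qv @ v) for rid, v in self._vecs.items()}


def dense_score(index: DenseIndex, q: str, recipe_id: str) -> float:
    return index.score(q, recipe_id)


# ---------------------------------------------------------------------------
# hybrid scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoredCandidate:
    """Per-recipe score breakdown accumulated through the pipeline stages."""

    recipe_id: str
    s_bm25: Optional[float] = None
    s_dense: Optional[float] = None
    s_hybrid: Optional[float] = None
    s_graph: Optional[float] = None
    s_cross: Optional[float] = None
    s_nutrition: Optional[float] = None
    phi: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "recipe_id": self.recipe_id,
            "s_bm25": self.s_bm25,
            "s_dense": self.s_dense,
            "s_hybrid": self.s_hybrid,
            "s_graph": self.s_graph,
            "s_cross": self.s_cross,
            "s_nutrition": self.s_nutrition,
            "phi": self.phi,
        }


def minmax_normalize(values: dict[str, float]) -> dict[str, float]:
    """Min-max to [0, 1] over the pool; a constant pool maps to all zeros."""
    if not values:
        return {}
    lo, hi = min(values.values()), max(values.values())
    if hi - lo <= 0:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def hybrid_retrieve(
    q: str,
    sparse: SparseIndex,
    dense: DenseIndex,
    policy: Optional[AlphaPolicy] = None,
    k: int = 200,
    lexicon: Optional[IntentLexicon] = None,
    alpha: Optional[float] = None,
) -> list[ScoredCandidate]:
    """Top-k candidates by the adaptive hybrid score.

    Raw BM25 and cosine scores are computed for every pooled recipe,
    min-max normalized over the pool, then mixed with the query's alpha.
    Ties break by ascending recipe id.  ``alpha`` overrides the policy
    (used by the fixed-alpha ablation).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    a = alpha if alpha is not None else compute_alpha(q, policy, lexicon)
    raw_sparse = sparse.scores(q)
    raw_dense = dense.scores(q)
    norm_s = minmax_normalize(raw_sparse)
    norm_d = minmax_normalize(raw_dense)
    cands = []
    for rid in raw_sparse:
        s_h = a * norm_d[rid] + (1.0 - a) * norm_s[rid]
        cands.append(ScoredCandidate(
            recipe_id=rid, s_bm25=raw_sparse[rid], s_dense=raw_dense[rid], s_hybrid=s_h,
        ))
    cands.sort(key=lambda c: (-c.s_hybrid, c.recipe_id))
    return cands[:k]


def build_indexes(
    corpus: RecipeCorpus, k1: float = 1.5, b: float = 0.75, embedder=None
) -> tuple[SparseIndex, DenseIndex]:
    return SparseIndex(corpus, k1=k1, b=b), DenseIndex(corpus, embedder=embedder)
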