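"""Intent refinement: fuzzy query -> structured ConstraintSet.

The primary mode is a deterministic phrase-lexicon parser: every lexicon
phrase found in the query contributes a partial ConstraintSet, and the
fragments are merged (conflicting macronutrient bounds intersect, so the
tighter bound wins).  A semantic fallback maps the query embedding onto
precomputed intent centroids by cosine similarity.  An external language
model can be plugged in behind the same ``query -> ConstraintSet`` contract
but is never required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Protocol, Sequence

import numpy as np

from .corpus import ConstraintSet


class ConfigurationError(ValueError):
    pass


def _canon(text: str) -> str:
    """Lowercase and treat hyphens/underscores as spaces for phrase matching."""
    return re.sub(r"[-_]", " ", text.lower())


@dataclass(frozen=True)
class IntentLexicon:
    """phrase -> partial-constraint mapping used by the rule parser.

    Phrases are stored lowercase with hyphens collapsed to spaces; matching
    is whole-word substring search on the canonicalized query.
    """

    fragments: Mapping[str, ConstraintSet]
    # phrases that signal an abstract intent (used by the retrieval-side
    # query classifier and the cross-scorer's term expansion)
    intent_phrases: frozenset[str] = frozenset()
    # intent phrase -> concrete food terms it implies, for term expansion
    expansions: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "fragments", {_canon(k): v for k, v in self.fragments.items()})
        object.__setattr__(
            self, "intent_phrases", frozenset(_canon(p) for p in self.intent_phrases)
        )
        object.__setattr__(self, "expansions", {_canon(k): v for k, v in self.expansions.items()})

    def matches(self, query: str) -> list[str]:
        """All lexicon phrases present in the query, longest first."""
        q = _canon(query)
        hits = [
            p for p in self.fragments
            if re.search(r"(?<![a-z])" + re.escape(p) + r"(?![a-z])", q)
        ]
        return sorted(hits, key=lambda p: (-len(p), p))

    def intent_hits(self, query: str) -> list[str]:
        q = _canon(query)
        return sorted(
            p for p in self.intent_phrases
            if re.search(r"(?<![a-z])" + re.escape(p) + r"(?![a-z])", q)
        )


def _cs(**kw) -> ConstraintSet:
    return ConstraintSet(**kw)


def default_lexicon() -> IntentLexicon:
    """Lexicon covering common fuzzy dietary phrases and allergen exclusions."""
    frag: dict[str, ConstraintSet] = {
        # satiety / energy markers
        "light": _cs(macro={"calories": {"max": 600}}),
        "filling": _cs(macro={"protein": {"min": 20}}),
        "hearty": _cs(macro={"calories": {"min": 500}}),
        "high protein": _cs(macro={"protein": {"min": 25}}),
        "low calorie": _cs(macro={"calories": {"max": 500}}),
        "low carb": _cs(macro={"carbohydrates": {"max": 30}}),
        "low fat": _cs(macro={"fat": {"max": 15}}),
        "high fiber": _cs(macro={"fiber": {"min": 8}}),
        # courses
        "breakfast": _cs(course="breakfast"),
        "lunch": _cs(course="lunch"),
        "dinner": _cs(course="dinner"),
        "snack": _cs(course="snack"),
        "dessert": _cs(course="dessert"),
        # health goals (abstract concepts resolved via the knowledge graph)
        "immune boosting": _cs(health_goals={"immune_boosting"}),
        "immune support": _cs(health_goals={"immune_boosting"}),
        "post workout": _cs(health_goals={"muscle_recovery"}, macro={"protein": {"min": 20}}),
        "muscle building": _cs(health_goals={"muscle_building"}, macro={"protein": {"min": 25}}),
        "weight loss": _cs(health_goals={"weight_loss"}, macro={"calories": {"max": 500}}),
        "heart healthy": _cs(health_goals={"heart_health"}),
        "energy boosting": _cs(health_goals={"energy"}),
        "gut friendly": _cs(health_goals={"gut_health"}),
        "healthy": _cs(health_goals={"general_health"}),
        "recovery": _cs(health_goals={"muscle_recovery"}),
        # diets
        "vegetarian": _cs(diet_tags={"vegetarian"}),
        "vegan": _cs(diet_tags={"vegan"}),
        "gluten free": _cs(diet_tags={"gluten_free"}),
        "dairy free": _cs(exclude={"dairy"}),
        "keto": _cs(diet_tags={"keto"}, macro={"carbohydrates": {"max": 20}}),
        # allergen exclusions
        "no nuts": _cs(exclude={"nuts"}),
        "nut free": _cs(exclude={"nuts"}),
        "nut allergy": _cs(exclude={"nuts"}),
        "no dairy": _cs(exclude={"dairy"}),
        "no gluten": _cs(exclude={"gluten"}),
        "no shellfish": _cs(exclude={"shellfish"}),
        "shellfish allergy": _cs(exclude={"shellfish"}),
        "no eggs": _cs(exclude={"egg"}),
        # practical context (kept as health-goal style markers)
        "quick": _cs(health_goals={"quick_prep"}),
        "family": _cs(health_goals={"family_style"}),
        "comfort food": _cs(health_goals={"comfort"}),
        "spicy": _cs(include=set(), health_goals={"spicy_craving"}),
    }
    intent_phrases = {
        "light", "filling", "hearty", "healthy", "recovery", "quick", "family",
        "immune boosting", "immune support", "post workout", "muscle building",
        "weight loss", "heart healthy", "energy boosting", "gut friendly",
        "low carb", "low calorie", "high protein", "high fiber", "low fat",
        "comfort food", "spicy", "vegetarian", "vegan", "keto",
    }
    expansions = {
        "immune boosting": ("turmeric", "ginger", "garlic", "citrus", "spinach"),
        "immune support": ("turmeric", "ginger", "garlic", "citrus", "spinach"),
        "post workout": ("chicken", "salmon", "egg", "quinoa", "greek yogurt"),
        "muscle building": ("chicken", "beef", "egg", "lentil", "cottage cheese"),
        "weight loss": ("salad", "zucchini", "cauliflower", "broccoli"),
        "heart healthy": ("salmon", "oat", "walnut", "olive oil", "avocado"),
        "energy boosting": ("oat", "banana", "quinoa", "sweet potato"),
        "gut friendly": ("yogurt", "kimchi", "oat", "banana"),
        "spicy": ("chili", "jalapeno", "sriracha", "cayenne"),
        "comfort food": ("cheese", "potato", "pasta", "butter"),
    }
    return IntentLexicon(frag, frozenset(intent_phrases), expansions)


def refine_intent(query: str, lexicon: Optional[IntentLexicon] = None) -> ConstraintSet:
    """Parse a fuzzy query into a ConstraintSet by lexicon phrase matching.

    Unmatched queries yield an empty ConstraintSet; the parse is deterministic
    and monotone — adding a phrase to the query never removes a constraint.
    """
    lexicon = lexicon if lexicon is not None else default_lexicon()
    out = ConstraintSet()
    for phrase in lexicon.matches(query):
        out = out.merge(lexicon.fragments[phrase])
    return out


class Embedder(Protocol):
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


@dataclass(frozen=True)
class IntentCentroids:
    """Named intents with precomputed unit-norm embedding centroids."""

    names: tuple[str, ...]
    vectors: np.ndarray          # (n_intents, dim), rows unit norm
    constraints: tuple[ConstraintSet, ...]

    def __post_init__(self):
        if self.vectors.ndim != 2 or len(self.names) != self.vectors.shape[0]:
            raise ConfigurationError("centroid matrix shape does not match names")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ConfigurationError("centroid vectors must be unit norm")

    @classmethod
    def from_texts(
        cls, items: Sequence[tuple[str, str, ConstraintSet]], embedder: Embedder
    ) -> "IntentCentroids":
        """Build centroids from (name, defining text, constraints) triples."""
        names, vecs, css = [], [], []
        for name, text, cs in items:
            names.append(name)
            vecs.append(embedder.embed(text))
            css.append(cs)
        return cls(tuple(names), np.asarray(vecs, dtype=float), tuple(css))


def semantic_fallback(
    query: str,
    centroids: IntentCentroids,
    embedder: Embedder,
    threshold: float = 0.3,
) -> ConstraintSet:
    """Map a query to the nearest intent centroid by cosine similarity.

    Ties break by centroid name (lexicographic); similarity below the
    threshold returns an empty ConstraintSet.
    """
    if len(centroids.names) == 0:
        raise ConfigurationError("no centroids configured")
    v = embedder.embed(query)
    if v.shape[0] != centroids.vectors.shape[1]:
        raise ConfigurationError(
            f"embedding dim {v.shape[0]} != centroid dim {centroids.vectors.shape[1]}"
        )
    sims = centroids.vectors @ v
    order = sorted(range(len(centroids.names)), key=lambda i: (-sims[i], centroids.names[i]))
    best = order[0]
    if sims[best] < threshold:
        return ConstraintSet()
    return centroids.constraints[best]


# optional hook: an external model implementing query -> ConstraintSet can be
# dropped in anywhere refine_intent is accepted
IntentParser = Callable[[str], ConstraintSet]
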