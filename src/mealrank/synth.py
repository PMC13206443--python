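"""Seeded synthetic recipe corpora, food graphs, and fuzzy-query benchmarks.

The generator emulates the structure of a fuzzy-intent recommendation
benchmark: a recipe corpus with per-course nutrient profiles, a concept ->
ingredient -> recipe knowledge graph, and a query set stratified into four
semantic categories (health goal 30%, taste/craving 26%, occasion/context
24%, hybrid/complex 20%) with planted ground-truth constraints and
relevance pools.

Planting guarantees two properties the evaluation relies on:

* every planted relevant recipe satisfies its query's ground-truth
  constraints (so a perfect system can reach CS-Rate 100%), and
* health-goal relevance is mediated by the knowledge graph — relevant
  recipes contain concept-promoted ingredients but never the abstract goal
  phrase itself, so lexical retrieval alone cannot resolve those queries.

A configurable fraction of recipes are deliberate violators: allergen
carriers, course-mismatched lookalikes (a beverage titled after a health
goal), and "hidden" violators whose ingredient list is clean but whose
preparation steps mention an excluded item.  Violator ids and kinds are
recorded in ``corpus.annotations``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import ConstraintSet, NutrientVector, Recipe, RecipeCorpus, normalize_ingredient
from .graph import FoodGraph, build_graph_from_schema
from .intent import default_lexicon, refine_intent
from .lexicons import CONCEPTS, GOAL_TO_CONCEPT, INGREDIENTS
from .rerank import IngredientOntology, check_constraints

CATEGORIES_BENCH = ("health_goal", "taste_craving", "occasion_context", "hybrid_complex")
DEFAULT_PROPORTIONS = (0.30, 0.26, 0.24, 0.20)

_COURSES = ("breakfast", "lunch", "dinner", "snack", "dessert")
# per-course calorie ranges (kcal) and mass ranges (g)
_COURSE_KCAL = {
    "breakfast": (250, 600), "lunch": (350, 800), "dinner": (400, 900),
    "snack": (100, 400), "dessert": (200, 600),
}
_MASS_RANGE = (150, 600)

_DISH_WORDS = ("bowl", "skillet", "bake", "stew", "plate", "medley", "roast", "salad")
_ADJECTIVES = ("rustic", "golden", "savory", "zesty", "fresh", "classic", "garden")

# goal phrase -> (health-goal key, signature concept) for health_goal queries
_GOAL_PHRASES = {
    "immune boosting": "immune_boosting",
    "post workout": "muscle_recovery",
    "muscle building": "muscle_building",
    "weight loss": "weight_loss",
    "heart healthy": "heart_health",
    "energy boosting": "energy",
    "gut friendly": "gut_health",
}

_TASTE_THEMES = {
    "spicy": ("chili", "jalapeno", "cayenne", "sriracha"),
    "creamy": ("cream", "butter", "cheese"),
    "sweet": ("honey", "maple syrup", "dark chocolate", "cinnamon"),
    "citrusy": ("lemon", "lime", "orange"),
}
_OCCASION_THEMES = {
    "quick": ("quick", "15 minute", "one pan"),
    "family": ("family", "sheet pan", "big batch"),
    "cozy": ("slow cooked", "comforting", "hearty"),
}


@dataclass(frozen=True)
class GeneratorConfig:
    corpus_size: int = 300
    benchmark_size: int = 150
    proportions: tuple[float, float, float, float] = DEFAULT_PROPORTIONS
    violation_rate: float = 0.2
    min_pool: int = 3
    max_pool: int = 8
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"category proportions must sum to 1, got {self.proportions}")
        if self.corpus_size < 0 or self.benchmark_size < 0:
            raise ValueError("sizes must be >= 0")
        if not 0.0 <= self.violation_rate <= 1.0:
            raise ValueError("violation rate must lie in [0, 1]")


@dataclass(frozen=True)
class BenchmarkQuery:
    query: str
    category: str
    constraints: ConstraintSet
    relevant_ids: frozenset[str]

    def to_json_dict(self) -> dict:
        return {
            "query": self.query,
            "category": self.category,
            "constraints": self.constraints.to_json_dict(),
            "relevant_ids": sorted(self.relevant_ids),
        }


def largest_remainder_counts(total: int, proportions: tuple[float, ...]) -> list[int]:
    """Integer category counts summing exactly to ``total``."""
    raw = [total * p for p in proportions]
    counts = [int(x) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def _concept_ingredients(concept: str, depth: int = 2) -> list[str]:
    """Ingredients reachable from a concept within ``depth`` schema hops."""
    out: list[str] = []
    frontier = [concept]
    for _ in range(depth):
        nxt = []
        for c in frontier:
            subs, ings = CONCEPTS.get(c, ((), ()))
            out.extend(normalize_ingredient(i) for i in ings)
            nxt.extend(subs)
        frontier = nxt
    seen: set[str] = set()
    return [i for i in out if not (i in seen or seen.add(i))]


_ALL_INGREDIENTS = sorted(normalize_ingredient(i) for i in INGREDIENTS)
_NUTS = sorted(i for i, c in INGREDIENTS.items() if "nuts" in c)
_DAIRY = sorted(i for i, c in INGREDIENTS.items() if "dairy" in c)
_LEXICON = default_lexicon()


def _nutrients_for(rng: np.random.Generator, course: str) -> tuple[NutrientVector, float]:
    protein = float(rng.uniform(5, 45))
    carbs = float(rng.uniform(15, 90))
    fat = float(rng.uniform(4, 40))
    fiber = float(rng.uniform(1, 12))
    kcal = 4 * protein + 4 * carbs + 9 * fat
    lo, hi = _COURSE_KCAL[course]
    # rescale macros so calories land in the course's range
    target = float(rng.uniform(lo, hi))
    scale = target / kcal
    protein, carbs, fat, fiber = (x * scale for x in (protein, carbs, fat, fiber))
    kcal = 4 * protein + 4 * carbs + 9 * fat
    mass = float(rng.uniform(*_MASS_RANGE))
    nv = NutrientVector(calories=round(kcal, 1), protein=round(protein, 1),
                        fat=round(fat, 1), carbohydrates=round(carbs, 1),
                        fiber=round(fiber, 1))
    return nv, round(mass, 1)


def _clamp_to_fragment(nv: NutrientVector, phrase: str) -> NutrientVector:
    """Adjust nutrients so the recipe satisfies the lexicon fragment for a
    goal phrase (e.g. a weight-loss recipe stays under the calorie cap)."""
    frag = _LEXICON.fragments.get(phrase)
    if frag is None:
        return nv
    vals = nv.as_dict()
    for name, bound in frag.macro.items():
        v = vals[name]
        if bound.max is not None and v > bound.max:
            vals[name] = round(bound.max * 0.85, 1)
        if bound.min is not None and v < bound.min:
            vals[name] = round(bound.min * 1.25, 1)
    if "calories" not in frag.macro:
        vals["calories"] = round(
            4 * vals["protein"] + 4 * vals["carbohydrates"] + 9 * vals["fat"], 1
        )
    return NutrientVector(**vals)


def _steps_for(rng: np.random.Generator, ingredients: list[str]) -> tuple[str, ...]:
    main = ingredients[0]
    rest = ", ".join(ingredients[1:4]) or main
    verbs = ("saute", "simmer", "roast", "toss", "combine", "sear")
    v1, v2 = rng.choice(verbs, size=2, replace=False)
    return (
        f"prep the {main} and {v1} until fragrant",
        f"{v2} with {rest} and season to taste",
        "plate and serve warm",
    )


def generate_corpus(cfg: GeneratorConfig) -> RecipeCorpus:
    """Seeded synthetic corpus with themed recipes and planted violators.

    ``corpus.annotations['planted_violators']`` maps recipe id -> violator
    kind ('allergen', 'course_mismatch', 'hidden_step').
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.corpus_size
    n_viol = round(n * cfg.violation_rate)
    recipes: list[Recipe] = []
    violators: dict[str, str] = {}

    goal_phrases = list(_GOAL_PHRASES)
    taste_keys = list(_TASTE_THEMES)
    occasion_keys = list(_OCCASION_THEMES)

    for i in range(n):
        rid = f"r{i:04d}"
        theme_kind = i % 4  # cycle themes for dense benchmark coverage
        course = _COURSES[i % len(_COURSES)] if theme_kind == 3 else None

        if theme_kind == 0:  # health-goal aligned
            phrase = goal_phrases[(i // 4) % len(goal_phrases)]
            concept = GOAL_TO_CONCEPT[_GOAL_PHRASES[phrase]]
            sig = _concept_ingredients(concept)
            picks = list(rng.choice(sig, size=min(2, len(sig)), replace=False))
            course = _COURSES[(i // 4) % len(_COURSES)]
            extra = [x for x in rng.choice(_ALL_INGREDIENTS, size=4, replace=False)
                     if x not in picks]
            ingredients = picks + extra[:3]
            title = f"{_ADJECTIVES[i % len(_ADJECTIVES)]} {picks[0]} {_DISH_WORDS[i % len(_DISH_WORDS)]}"
            nv, mass = _nutrients_for(rng, course)
            nv = _clamp_to_fragment(nv, phrase)
        elif theme_kind == 1:  # taste-themed: adjective appears in the title
            taste = taste_keys[(i // 4) % len(taste_keys)]
            sig = list(_TASTE_THEMES[taste])
            picks = list(rng.choice(sig, size=min(2, len(sig)), replace=False))
            course = _COURSES[(i // 4) % len(_COURSES)]
            extra = [x for x in rng.choice(_ALL_INGREDIENTS, size=4, replace=False)
                     if x not in picks]
            ingredients = picks + extra[:3]
            title = f"{taste} {picks[0]} {_DISH_WORDS[i % len(_DISH_WORDS)]}"
            nv, mass = _nutrients_for(rng, course)
        elif theme_kind == 2:  # occasion-themed: context marker in the title
            occ = occasion_keys[(i // 4) % len(occasion_keys)]
            marker = _OCCASION_THEMES[occ][i % len(_OCCASION_THEMES[occ])]
            course = _COURSES[(i // 4) % len(_COURSES)]
            picks = list(rng.choice(_ALL_INGREDIENTS, size=4, replace=False))
            ingredients = picks
            title = f"{marker} {picks[0]} {_DISH_WORDS[i % len(_DISH_WORDS)]}"
            nv, mass = _nutrients_for(rng, course)
        else:  # generic filler
            picks = list(rng.choice(_ALL_INGREDIENTS, size=5, replace=False))
            ingredients = picks
            title = f"{_ADJECTIVES[i % len(_ADJECTIVES)]} {picks[0]} {_DISH_WORDS[(i // 2) % len(_DISH_WORDS)]}"
            nv, mass = _nutrients_for(rng, course)

        steps = _steps_for(rng, ingredients)

        if i < n_viol:
            kind = ("allergen", "course_mismatch", "hidden_step")[i % 3]
            if kind == "allergen":
                allergen = (_NUTS + _DAIRY)[i % (len(_NUTS) + len(_DAIRY))]
                if allergen not in ingredients:
                    ingredients = ingredients[:-1] + [allergen]
            elif kind == "course_mismatch":
                # beverage lookalike: attractive title, off-course attribute
                phrase = goal_phrases[i % len(goal_phrases)]
                title = f"{phrase} smoothie"
                course = "snack"
                steps = ("add everything to the blender",
                         "blend until smooth and pour into a glass")
            else:  # hidden_step: clean list, allergen only in the steps
                nut = _NUTS[i % len(_NUTS)]
                ingredients = [x for x in ingredients
                               if not any(nut in x for nut in _NUTS)] or ["rice"]
                steps = steps[:-1] + (f"garnish with crushed {nut} before serving",)
            violators[rid] = kind

        recipes.append(Recipe(
            id=rid, title=title, course=course, ingredients=tuple(ingredients),
            steps=steps, total_mass_g=mass, nutrients=nv,
        ))

    corpus = RecipeCorpus(recipes)
    corpus.annotations["planted_violators"] = violators
    return corpus


def generate_graph(corpus: RecipeCorpus, cfg: GeneratorConfig) -> FoodGraph:
    """Concept schema plus ingredient->recipe containment edges.

    Deterministic given the corpus; always includes the immune-support ->
    anti-inflammatory -> {turmeric, ginger, garlic} motif from the schema.
    """
    return build_graph_from_schema(corpus)


# ---------------------------------------------------------------------------
# benchmark generation
# ---------------------------------------------------------------------------

def _satisfies(recipe: Recipe, cons: ConstraintSet, onto: IngredientOntology) -> bool:
    return check_constraints(recipe, cons, onto).passed


def _plant_pool(
    corpus: RecipeCorpus, cons: ConstraintSet, signature_terms: list[str],
    onto: IngredientOntology, rng: np.random.Generator, cfg: GeneratorConfig,
    require_signature: bool = True,
) -> list[str]:
    """Relevant pool: constraint-satisfying recipes carrying a signature term
    (in ingredients or title)."""
    hits = []
    for r in corpus:
        if not _satisfies(r, cons, onto):
            continue
        text = r.title.lower() + " " + " ".join(r.ingredients)
        if not require_signature or any(t in text for t in signature_terms):
            hits.append(r.id)
    if not hits:
        return []
    size = min(len(hits), int(rng.integers(cfg.min_pool, cfg.max_pool + 1)))
    return sorted(rng.choice(hits, size=size, replace=False).tolist())


def _query_templates(rng: np.random.Generator):
    """Yield (category, query, signature terms, require_signature) template
    instances, cyclically and deterministically."""
    courses = ("dinner", "lunch", "breakfast")
    health, taste, occasion, hybrid = [], [], [], []
    for phrase in _GOAL_PHRASES:
        concept = GOAL_TO_CONCEPT[_GOAL_PHRASES[phrase]]
        sig = _concept_ingredients(concept)
        for c in courses:
            health.append((f"{phrase} {c}", sig))
            health.append((f"{phrase} meal for {c}", sig))
    for adj, sig in _TASTE_THEMES.items():
        for c in courses:
            taste.append((f"something {adj} for {c}", list(sig) + [adj]))
            taste.append((f"{adj} craving tonight", list(sig) + [adj]))
    for occ, markers in _OCCASION_THEMES.items():
        for c in courses:
            occasion.append((f"{occ} {c}", list(markers)))
            occasion.append((f"{occ} meal for {c} tonight", list(markers)))
    hybrid_specs = [
        ("light but filling {c}", []),
        ("healthy {c} no nuts", []),
        ("quick vegetarian {c}", ["quick"]),
        ("low carb {c} without dairy", []),
        ("spicy {c} gluten free", ["chili", "jalapeno", "cayenne", "sriracha", "spicy"]),
        ("heart healthy {c} no shellfish", _concept_ingredients("heart_health")),
    ]
    for tmpl, sig in hybrid_specs:
        for c in courses:
            hybrid.append((tmpl.format(c=c), sig))
    return {
        "health_goal": health, "taste_craving": taste,
        "occasion_context": occasion, "hybrid_complex": hybrid,
    }


def generate_benchmark(
    corpus: RecipeCorpus, graph: FoodGraph, cfg: GeneratorConfig
) -> list[BenchmarkQuery]:
    """Stratified fuzzy-query benchmark with planted relevance.

    Category counts follow the configured proportions with largest-remainder
    rounding.  Ground-truth constraints are the lexicon parse of the query
    (so the benchmark is exactly parseable); relevant pools contain only
    constraint-satisfying recipes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    onto = IngredientOntology.default()
    counts = largest_remainder_counts(cfg.benchmark_size, cfg.proportions)
    templates = _query_templates(rng)
    out: list[BenchmarkQuery] = []
    for cat, want in zip(CATEGORIES_BENCH, counts):
        made = 0
        pool_templates = templates[cat]
        attempt = 0
        while made < want:
            base_q, sig = pool_templates[attempt % len(pool_templates)]
            attempt += 1
            # vary surface form on repeat passes so queries stay distinct
            rep = (attempt - 1) // len(pool_templates)
            q = base_q if rep == 0 else f"{base_q} please ({rep})"
            cons = refine_intent(base_q, _LEXICON)
            require_sig = bool(sig)
            rel = _plant_pool(corpus, cons, [s.lower() for s in sig], onto, rng, cfg,
                              require_signature=require_sig)
            if not rel:
                rel = _plant_pool(corpus, cons, [], onto, rng, cfg,
                                  require_signature=False)
            if not rel:
                if attempt > 10 * len(pool_templates):
                    raise RuntimeError(
                        f"corpus too small to plant relevance for category {cat!r}"
                    )
                continue
            out.append(BenchmarkQuery(q, cat, cons, frozenset(rel)))
            made += 1
    return out


def write_benchmark(queries: list[BenchmarkQuery], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for q in queries:
            fh.write(json.dumps(q.to_json_dict(), ensure_ascii=False, sort_keys=True) + "\n")


def read_benchmark(path) -> list[BenchmarkQuery]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            out.append(BenchmarkQuery(
                query=rec["query"], category=rec["category"],
                constraints=ConstraintSet(**rec["constraints"]),
                relevant_ids=frozenset(rec["relevant_ids"]),
            ))
    return out
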