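"""Semantic reranking and deterministic hard-constraint filtering.

The cross-scorer slot accepts any callable scoring the full query/recipe
interaction in [0, 1]; the shipped default is a deterministic token-overlap
scorer over the query tokens plus lexicon-expanded intent terms.  Hard
filtering is a veto: a candidate violating any negative constraint —
excluded ingredient (directly, by category expansion, or as part of a
compound name), missing mandatory ingredient, wrong course, macro bound, or
diet-rule conflict — is discarded, and every violation is recorded in an
auditable verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional
import warnings

import yaml

from .corpus import ConstraintSet, Recipe, RecipeCorpus, normalize_ingredient
from .intent import IntentLexicon, default_lexicon
from .lexicons import CATEGORIES, DIET_RULES
from .retrieval import ScoredCandidate, tokenize

_STOPWORDS = frozenset({
    "a", "an", "the", "for", "with", "and", "or", "but", "of", "to", "in",
    "on", "something", "some", "me", "my", "i", "please", "meal", "recipe",
    "food", "dish",
})


@dataclass(frozen=True)
class IngredientOntology:
    """category -> member ingredients, plus diet tag -> forbidden categories."""

    categories: Mapping[str, frozenset[str]]
    diet_rules: Mapping[str, tuple[str, ...]]

    @classmethod
    def default(cls) -> "IngredientOntology":
        return cls(CATEGORIES, DIET_RULES)

    @classmethod
    def from_yaml(cls, path) -> "IngredientOntology":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        cats = {
            normalize_ingredient(c): frozenset(normalize_ingredient(m) for m in members)
            for c, members in (data.get("categories") or {}).items()
        }
        rules = {t: tuple(v) for t, v in (data.get("diet_rules") or {}).items()}
        return cls(cats, rules)

    def expand(self, name: str) -> frozenset[str]:
        """Expand a category name to its members; a plain ingredient expands
        to itself.  Unknown names are treated as literal ingredients."""
        name = normalize_ingredient(name)
        if name in self.categories:
            return self.categories[name]
        return frozenset({name})

    def forbidden_for_diets(self, diet_tags: Iterable[str]) -> frozenset[str]:
        out: set[str] = set()
        for tag in diet_tags:
            tag_key = tag.replace(" ", "_")
            if tag_key not in self.diet_rules:
                warnings.warn(f"no diet rule for tag {tag!r}; tag ignored")
                continue
            for cat in self.diet_rules[tag_key]:
                out |= self.expand(cat)
        return frozenset(out)


def _ingredient_matches(excluded: str, ingredient: str) -> bool:
    """True when the excluded name equals the ingredient or occurs inside a
    compound name on a word boundary ("peanut" matches "peanut butter")."""
    if excluded == ingredient:
        return True
    return excluded in ingredient.split() or f" {excluded} " in f" {ingredient} "


@dataclass
class FilterVerdict:
    recipe_id: str
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def as_dict(self) -> dict:
        return {
            "recipe_id": self.recipe_id,
            "passed": self.passed,
            "violations": [{"constraint": c, "evidence": e} for c, e in self.violations],
        }


def check_constraints(
    recipe: Recipe, constraints: ConstraintSet, ontology: Optional[IngredientOntology] = None
) -> FilterVerdict:
    """Evaluate every hard constraint against one recipe."""
    ontology = ontology if ontology is not None else IngredientOntology.default()
    v = FilterVerdict(recipe_id=recipe.id)

    # (a) exclusions: direct, category-expanded, and compound-name matches
    for exc in sorted(constraints.exclude):
        members = ontology.expand(exc)  # unknown category names fall back to literal
        for ing in recipe.ingredients:
            if any(_ingredient_matches(m, ing) for m in members):
                v.violations.append((f"exclude:{exc}", ing))
                break

    # (b) mandatory inclusions
    for inc in sorted(constraints.include):
        if not any(_ingredient_matches(inc, ing) for ing in recipe.ingredients):
            v.violations.append((f"include:{inc}", "absent"))

    # (c) course
    if constraints.course is not None and recipe.course != constraints.course:
        v.violations.append((f"course:{constraints.course}", recipe.course))

    # (d) per-meal macro bounds
    nut = recipe.nutrients.as_dict()
    for name, bound in sorted(constraints.macro.items()):
        if name not in nut:
            v.violations.append((f"macro:{name}", "unknown nutrient"))
            continue
        if not bound.contains(nut[name]):
            v.violations.append((f"macro:{name}", f"{nut[name]:g}"))

    # (e) diet-tag compatibility via ontology rules
    forbidden = ontology.forbidden_for_diets(constraints.diet_tags)
    if forbidden:
        for ing in recipe.ingredients:
            if any(_ingredient_matches(m, ing) for m in forbidden):
                v.violations.append(("diet_tags", ing))
                break

    return v


def hard_filter(
    candidates: list[ScoredCandidate],
    constraints: ConstraintSet,
    corpus: RecipeCorpus,
    ontology: Optional[IngredientOntology] = None,
) -> tuple[list[ScoredCandidate], list[FilterVerdict]]:
    """Discard every candidate violating a hard constraint.

    Returns survivors (input order preserved) and a verdict per input
    candidate.  Filtering is idempotent and order-independent.
    """
    ontology = ontology if ontology is not None else IngredientOntology.default()
    survivors, verdicts = [], []
    for cand in candidates:
        verdict = check_constraints(corpus[cand.recipe_id], constraints, ontology)
        verdicts.append(verdict)
        if verdict.passed:
            survivors.append(cand)
    return survivors, verdicts


# ---------------------------------------------------------------------------
# cross-scorer
# ---------------------------------------------------------------------------

def expanded_query_terms(q: str, lexicon: Optional[IntentLexicon] = None) -> frozenset[str]:
    """Content tokens of the query plus concrete food terms implied by any
    matched intent phrase (e.g. an immune-support phrase implies turmeric,
    ginger, garlic)."""
    lexicon = lexicon if lexicon is not None else default_lexicon()
    terms = {t for t in tokenize(q) if t not in _STOPWORDS}
    for phrase in lexicon.intent_hits(q):
        for term in lexicon.expansions.get(phrase, ()):
            terms.update(tokenize(term))
    return frozenset(terms)


def cross_score(
    q: str, recipe: Recipe, lexicon: Optional[IntentLexicon] = None
) -> float:
    """Deterministic default cross-scorer: fraction of expanded query-side
    terms present in the recipe text, in [0, 1].  A learned cross-encoder can
    replace this behind the same (q, r) -> [0, 1] contract."""
    terms = expanded_query_terms(q, lexicon)
    if not terms:
        return 0.0
    doc = frozenset(tokenize(recipe.text))
    return len(terms & doc) / len(terms)
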