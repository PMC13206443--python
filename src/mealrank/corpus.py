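"""Core domain types and corpus I/O.

A recipe couples structured attributes (normalized ingredient list, course,
total mass) with a 5-dimensional nutrient vector (calories, protein, fat,
carbohydrates, fiber) and free text (title + ingredients + steps).  User
requirements are expressed as a :class:`ConstraintSet`: dietary tags,
mandatory/forbidden ingredients, per-meal macronutrient bounds, a meal
course, and abstract health goals.

Corpora are stored as JSON Lines, one recipe object per line, UTF-8.
"""

from __future__ import annotations

import json
import warnings
from typing import Iterable, Iterator, Mapping, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

COURSES = ("breakfast", "lunch", "dinner", "snack", "dessert")

NUTRIENT_FIELDS = ("calories", "protein", "fat", "carbohydrates", "fiber")


class CorpusValidationError(ValueError):
    """A recipe record violates a domain invariant."""


def normalize_ingredient(name: str) -> str:
    """Lowercase, trim, collapse whitespace and strip a plural 's'.

    Normalization happens once at load time so that exclusion matching
    downstream is a deterministic string comparison.
    """
    tokens = name.strip().lower().split()
    out = []
    for tok in tokens:
        # naive singularization: "berries" -> "berry", "tomatoes" -> "tomato",
        # "eggs" -> "egg"; keep short tokens and -ss words ("swiss") intact
        if tok.endswith("ies") and len(tok) > 4:
            tok = tok[:-3] + "y"
        elif len(tok) > 4 and any(
            tok.endswith(suf) for suf in ("oes", "ches", "shes", "sses", "xes", "zes")
        ):
            tok = tok[:-2]
        elif tok.endswith("s") and not tok.endswith("ss") and len(tok) > 3:
            tok = tok[:-1]
        out.append(tok)
    return " ".join(out)


class NutrientVector(BaseModel):
    """Per-recipe nutrient amounts: kcal for calories, grams otherwise."""

    model_config = ConfigDict(frozen=True)

    calories: float = Field(ge=0)
    protein: float = Field(ge=0)
    fat: float = Field(ge=0)
    carbohydrates: float = Field(ge=0)
    fiber: float = Field(ge=0)

    @field_validator("*")
    @classmethod
    def _finite(cls, v: float) -> float:
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("nutrient values must be finite")
        return v

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in NUTRIENT_FIELDS}


class Recipe(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    title: str
    course: str
    ingredients: tuple[str, ...]
    steps: tuple[str, ...] = ()
    total_mass_g: float = Field(gt=0)
    nutrients: NutrientVector

    @field_validator("course")
    @classmethod
    def _known_course(cls, v: str) -> str:
        if v not in COURSES:
            raise ValueError(f"unknown course {v!r}; expected one of {COURSES}")
        return v

    @field_validator("ingredients")
    @classmethod
    def _normalize(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("ingredients must be non-empty")
        return tuple(normalize_ingredient(x) for x in v)

    @property
    def text(self) -> str:
        """Unstructured text T(r): title, ingredients and steps concatenated."""
        return " ".join([self.title, *self.ingredients, *self.steps])


class MacroBound(BaseModel):
    model_config = ConfigDict(frozen=True)

    min: Optional[float] = None
    max: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "MacroBound":
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"macro bound min {self.min} > max {self.max}")
        return self

    def tighten(self, other: "MacroBound") -> "MacroBound":
        """Intersection of two bounds — the tighter constraint wins."""
        lo = max((b for b in (self.min, other.min) if b is not None), default=None)
        hi = min((b for b in (self.max, other.max) if b is not None), default=None)
        return MacroBound(min=lo, max=hi)

    def contains(self, value: float) -> bool:
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value > self.max:
            return False
        return True


class ConstraintSet(BaseModel):
    """Structured dietary constraints extracted from a fuzzy query."""

    model_config = ConfigDict(frozen=True)

    diet_tags: frozenset[str] = frozenset()
    include: frozenset[str] = frozenset()
    exclude: frozenset[str] = frozenset()
    macro: Mapping[str, MacroBound] = Field(default_factory=dict)
    course: Optional[str] = None
    health_goals: frozenset[str] = frozenset()

    @field_validator("course")
    @classmethod
    def _known_course(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in COURSES:
            raise ValueError(f"unknown course {v!r}")
        return v

    @field_validator("include", "exclude", "diet_tags", "health_goals", mode="before")
    @classmethod
    def _norm_sets(cls, v) -> frozenset[str]:
        return frozenset(normalize_ingredient(x) for x in v)

    @field_validator("macro", mode="before")
    @classmethod
    def _coerce_macro(cls, v):
        return {k: b if isinstance(b, MacroBound) else MacroBound(**b) for k, b in dict(v).items()}

    def is_empty(self) -> bool:
        return not (
            self.diet_tags or self.include or self.exclude or self.macro
            or self.course or self.health_goals
        )

    def merge(self, other: "ConstraintSet") -> "ConstraintSet":
        """Union of constraints; conflicting macro bounds take the tighter one.

        Course conflicts resolve in favour of ``self`` (first extraction wins);
        in practice lexicon fragments never disagree on course.
        """
        macro = dict(self.macro)
        for k, b in other.macro.items():
            macro[k] = macro[k].tighten(b) if k in macro else b
        return ConstraintSet(
            diet_tags=self.diet_tags | other.diet_tags,
            include=self.include | other.include,
            exclude=self.exclude | other.exclude,
            macro=macro,
            course=self.course or other.course,
            health_goals=self.health_goals | other.health_goals,
        )

    def to_json_dict(self) -> dict:
        return {
            "diet_tags": sorted(self.diet_tags),
            "include": sorted(self.include),
            "exclude": sorted(self.exclude),
            "macro": {
                k: {kk: vv for kk, vv in (("min", b.min), ("max", b.max)) if vv is not None}
                for k, b in sorted(self.macro.items())
            },
            "course": self.course,
            "health_goals": sorted(self.health_goals),
        }


class RecipeCorpus:
    """Ordered recipe collection with id lookup.

    ``annotations`` carries generator-side metadata (e.g. which recipes were
    planted as constraint violators); it is not serialized and does not
    participate in equality, so write/read round-trips compare clean.
    """

    def __init__(self, recipes: Iterable[Recipe] = (), annotations: Optional[dict] = None):
        self._recipes: list[Recipe] = []
        self._by_id: dict[str, Recipe] = {}
        for r in recipes:
            if r.id in self._by_id:
                raise CorpusValidationError(f"duplicate recipe id {r.id!r}")
            self._recipes.append(r)
            self._by_id[r.id] = r
        self.annotations: dict = annotations or {}

    def __len__(self) -> int:
        return len(self._recipes)

    def __iter__(self) -> Iterator[Recipe]:
        return iter(self._recipes)

    def __getitem__(self, recipe_id: str) -> Recipe:
        return self._by_id[recipe_id]

    def __contains__(self, recipe_id: str) -> bool:
        return recipe_id in self._by_id

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecipeCorpus):
            return NotImplemented
        return self._recipes == other._recipes

    def ids(self) -> list[str]:
        return [r.id for r in self._recipes]


_REQUIRED = ("id", "title", "course", "ingredients", "total_mass_g", "nutrients")


def _recipe_from_record(rec: dict, lineno: int) -> Recipe:
    for field in _REQUIRED:
        if field not in rec:
            raise CorpusValidationError(f"line {lineno}: missing required field {field!r}")
    nut = rec["nutrients"]
    extra = set(nut) - set(NUTRIENT_FIELDS)
    if extra:
        warnings.warn(f"line {lineno}: ignoring extra nutrient keys {sorted(extra)}")
        nut = {k: v for k, v in nut.items() if k in NUTRIENT_FIELDS}
    try:
        return Recipe(
            id=rec["id"],
            title=rec["title"],
            course=rec["course"],
            ingredients=tuple(rec["ingredients"]),
            steps=tuple(rec.get("steps", ())),
            total_mass_g=rec["total_mass_g"],
            nutrients=NutrientVector(**nut),
        )
    except ValueError as exc:
        raise CorpusValidationError(f"line {lineno}: {exc}") from exc


def read_corpus(path) -> RecipeCorpus:
    """Read a JSON Lines recipe corpus, validating every record.

    Raises :class:`CorpusValidationError` naming the offending line for the
    first malformed record.
    """
    recipes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusValidationError(f"line {lineno}: invalid JSON ({exc})") from exc
            recipes.append(_recipe_from_record(rec, lineno))
    return RecipeCorpus(recipes)


def write_corpus(corpus: RecipeCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in corpus:
            rec = {
                "id": r.id,
                "title": r.title,
                "course": r.course,
                "ingredients": list(r.ingredients),
                "steps": list(r.steps),
                "total_mass_g": r.total_mass_g,
                "nutrients": r.nutrients.as_dict(),
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
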