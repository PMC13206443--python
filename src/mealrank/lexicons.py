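"""Built-in food vocabulary shared across modules.

Roughly 80 ingredients with category tags, a set of common dish names, and
the health-concept schema (concept -> promoted sub-concepts/ingredients) used
by the knowledge-graph builder and the synthetic generator.  Categories feed
the ingredient ontology used for allergen/diet exclusion.
"""

from __future__ import annotations

# ingredient -> categories it belongs to
INGREDIENTS: dict[str, tuple[str, ...]] = {
    # proteins / meat / fish
    "chicken": ("meat", "animal"),
    "beef": ("meat", "animal", "red meat"),
    "pork": ("meat", "animal", "red meat"),
    "turkey": ("meat", "animal"),
    "salmon": ("fish", "animal"),
    "tuna": ("fish", "animal"),
    "cod": ("fish", "animal"),
    "shrimp": ("shellfish", "animal"),
    "crab": ("shellfish", "animal"),
    "mussel": ("shellfish", "animal"),
    "egg": ("egg", "animal"),
    "tofu": ("soy",),
    "tempeh": ("soy",),
    # dairy
    "milk": ("dairy", "animal"),
    "butter": ("dairy", "animal"),
    "cheese": ("dairy", "animal"),
    "cream": ("dairy", "animal"),
    "yogurt": ("dairy", "animal"),
    "greek yogurt": ("dairy", "animal"),
    "cottage cheese": ("dairy", "animal"),
    "parmesan": ("dairy", "animal"),
    "mozzarella": ("dairy", "animal"),
    # nuts & seeds
    "peanut": ("nuts",),
    "peanut butter": ("nuts",),
    "almond": ("nuts",),
    "walnut": ("nuts",),
    "cashew": ("nuts",),
    "pecan": ("nuts",),
    "hazelnut": ("nuts",),
    "chia seed": ("seeds",),
    "sesame seed": ("seeds",),
    "sunflower seed": ("seeds",),
    # grains (gluten-bearing and not)
    "wheat flour": ("gluten", "grain"),
    "bread": ("gluten", "grain"),
    "pasta": ("gluten", "grain"),
    "noodle": ("gluten", "grain"),
    "barley": ("gluten", "grain"),
    "couscous": ("gluten", "grain"),
    "rice": ("grain",),
    "brown rice": ("grain",),
    "quinoa": ("grain",),
    "oat": ("grain",),
    "cornmeal": ("grain",),
    # legumes
    "lentil": ("legume",),
    "chickpea": ("legume",),
    "black bean": ("legume",),
    "kidney bean": ("legume",),
    "edamame": ("legume", "soy"),
    # vegetables
    "spinach": ("vegetable", "leafy green"),
    "kale": ("vegetable", "leafy green"),
    "broccoli": ("vegetable",),
    "cauliflower": ("vegetable",),
    "carrot": ("vegetable",),
    "zucchini": ("vegetable",),
    "bell pepper": ("vegetable",),
    "tomato": ("vegetable",),
    "onion": ("vegetable",),
    "mushroom": ("vegetable",),
    "sweet potato": ("vegetable", "starchy"),
    "potato": ("vegetable", "starchy"),
    "celery": ("vegetable",),
    "cucumber": ("vegetable",),
    "beet": ("vegetable",),
    "pea": ("vegetable",),
    # fruit
    "banana": ("fruit",),
    "apple": ("fruit",),
    "blueberry": ("fruit", "berry"),
    "strawberry": ("fruit", "berry"),
    "raspberry": ("fruit", "berry"),
    "orange": ("fruit", "citrus"),
    "lemon": ("fruit", "citrus"),
    "lime": ("fruit", "citrus"),
    "avocado": ("fruit",),
    "mango": ("fruit",),
    "raisin": ("fruit",),
    # aromatics / spices / condiments
    "garlic": ("aromatic",),
    "ginger": ("aromatic",),
    "turmeric": ("spice",),
    "cumin": ("spice",),
    "paprika": ("spice",),
    "cinnamon": ("spice",),
    "chili": ("spice",),
    "jalapeno": ("spice",),
    "cayenne": ("spice",),
    "basil": ("herb",),
    "cilantro": ("herb",),
    "parsley": ("herb",),
    "olive oil": ("oil",),
    "coconut oil": ("oil",),
    "honey": ("sweetener",),
    "maple syrup": ("sweetener",),
    "sugar": ("sweetener",),
    "dark chocolate": ("sweetener",),
    "soy sauce": ("soy", "condiment"),
    "sriracha": ("spice", "condiment"),
}

# categories whose members an exclusion like "nuts" or "dairy" expands to;
# keys are stored in the same normalized form as corpus ingredients
from .corpus import normalize_ingredient as _norm

CATEGORIES: dict[str, frozenset[str]] = {}
for _ing, _cats in INGREDIENTS.items():
    for _c in _cats:
        CATEGORIES.setdefault(_norm(_c), set()).add(_norm(_ing))  # type: ignore[arg-type]
CATEGORIES = {c: frozenset(m) for c, m in CATEGORIES.items()}

# diet tag -> categories forbidden under that diet
DIET_RULES: dict[str, tuple[str, ...]] = {
    "vegetarian": ("meat", "fish", "shellfish"),
    "vegan": ("meat", "fish", "shellfish", "dairy", "egg"),
    "pescatarian": ("meat",),
    "gluten_free": ("gluten",),
    "dairy_free": ("dairy",),
    "nut_free": ("nuts",),
    "keto": ("sweetener",),
}

# short dish names a user might type verbatim
DISH_NAMES: frozenset[str] = frozenset({
    "pizza", "pasta", "soup", "salad", "stew", "curry", "risotto", "tacos",
    "taco", "burger", "sandwich", "omelette", "pancakes", "pancake",
    "smoothie", "stir fry", "lasagna", "sushi", "ramen", "chili",
    "casserole", "frittata", "burrito", "quiche", "paella", "wrap",
})

# health concept graph schema: concept -> (promoted concepts, promoted ingredients)
CONCEPTS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "immune_system": (("anti_inflammatory", "antioxidant_rich"), ()),
    "anti_inflammatory": ((), ("turmeric", "ginger", "garlic", "salmon", "spinach")),
    "antioxidant_rich": ((), ("blueberry", "kale", "beet", "dark chocolate")),
    "muscle_recovery": (("high_protein_food",), ("banana", "sweet potato")),
    "muscle_building": (("high_protein_food",), ()),
    "high_protein_food": ((), ("chicken", "salmon", "egg", "lentil", "greek yogurt", "tofu")),
    "weight_loss": (("low_energy_density",), ()),
    "low_energy_density": ((), ("zucchini", "cauliflower", "cucumber", "spinach", "broccoli")),
    "heart_health": (("omega3_rich", "whole_grain"), ()),
    "omega3_rich": ((), ("salmon", "walnut", "chia seed")),
    "whole_grain": ((), ("oat", "quinoa", "brown rice")),
    "energy": (("whole_grain",), ("banana", "sweet potato", "oat")),
    "gut_health": (("fermented_food", "high_fiber_food"), ()),
    "fermented_food": ((), ("yogurt", "tempeh")),
    "high_fiber_food": ((), ("lentil", "black bean", "oat", "raspberry", "chickpea")),
    "general_health": (("antioxidant_rich", "whole_grain"), ()),
}

# health-goal name (as produced by the intent lexicon) -> entry concept
GOAL_TO_CONCEPT: dict[str, str] = {
    "immune_boosting": "immune_system",
    "muscle_recovery": "muscle_recovery",
    "muscle_building": "muscle_building",
    "weight_loss": "weight_loss",
    "heart_health": "heart_health",
    "energy": "energy",
    "gut_health": "gut_health",
    "general_health": "general_health",
}
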