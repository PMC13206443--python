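import pytest

from mealrank.corpus import NutrientVector, Recipe, RecipeCorpus
from mealrank.retrieval import build_indexes
from mealrank.synth import GeneratorConfig, generate_benchmark, generate_corpus, generate_graph


def make_recipe(rid, title="test dish", course="dinner", ingredients=("rice", "chicken"),
                steps=("cook", "serve"), mass=400.0, calories=500.0, protein=30.0,
                fat=15.0, carbohydrates=45.0, fiber=5.0):
    return Recipe(
        id=rid, title=title, course=course, ingredients=tuple(ingredients),
        steps=tuple(steps), total_mass_g=mass,
        nutrients=NutrientVector(calories=calories, protein=protein, fat=fat,
                                 carbohydrates=carbohydrates, fiber=fiber),
    )


@pytest.fixture(scope="session")
def small_corpus():
    """Three hand-authored recipes with distinct vocabularies."""
    return RecipeCorpus([
        make_recipe("a01", title="garlic chicken skillet",
                    ingredients=("chicken", "garlic", "olive oil"),
                    steps=("sear the chicken", "add garlic")),
        make_recipe("a02", title="peanut butter oat bars", course="snack",
                    ingredients=("peanut butter", "oat", "honey"),
                    steps=("mix", "press", "chill")),
        make_recipe("a03", title="turmeric ginger salmon", course="dinner",
                    ingredients=("salmon", "turmeric", "ginger", "spinach"),
                    steps=("season the salmon", "roast with spinach")),
    ])


@pytest.fixture(scope="session")
def gen_cfg():
    return GeneratorConfig(corpus_size=150, benchmark_size=24, seed=7)


@pytest.fixture(scope="session")
def gen_corpus(gen_cfg):
    return generate_corpus(gen_cfg)


@pytest.fixture(scope="session")
def gen_graph(gen_cfg, gen_corpus):
    return generate_graph(gen_corpus, gen_cfg)


@pytest.fixture(scope="session")
def gen_benchmark(gen_cfg, gen_corpus, gen_graph):
    return generate_benchmark(gen_corpus, gen_graph, gen_cfg)


@pytest.fixture(scope="session")
def gen_indexes(gen_corpus):
    return build_indexes(gen_corpus)
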