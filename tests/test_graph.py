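"""Knowledge-graph construction, traversal bounds and path-decay scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mealrank.graph import (
    FoodGraph, GraphSchemaError, PathScore, enumerate_paths, graph_score,
    map_query_to_concepts, read_graph, source_candidates, write_graph,
)
from mealrank.pipeline import DEFAULT_CONCEPT_LEXICON
from mealrank.retrieval import ScoredCandidate


def chain_graph():
    """concept -> concept -> ingredient -> recipe chain plus a shortcut."""
    g = FoodGraph()
    g.add_node("immune_system", "concept")
    g.add_node("anti_inflammatory", "concept")
    g.add_node("ginger", "ingredient")
    g.add_node("r1", "recipe")
    g.add_edge("immune_system", "promotes", "anti_inflammatory")
    g.add_edge("anti_inflammatory", "has_ingredient", "ginger")
    g.add_edge("ginger", "contains_ingredient", "r1")
    g.add_edge("immune_system", "has_ingredient", "ginger")  # shortcut
    return g


def dfs_paths(adj, source, target, max_len):
    """Independent recursive enumeration of simple paths (the oracle)."""
    out = []

    def walk(node, path):
        if len(path) - 1 > max_len:
            return
        if node == target:
            out.append(tuple(path))
            return
        for nxt in sorted(adj.get(node, ())):
            if nxt not in path:
                walk(nxt, path + [nxt])

    walk(source, [source])
    return [p for p in out if 1 <= len(p) - 1 <= max_len]


class TestSchema:
    def test_edge_type_constraints_enforced(self):
        g = FoodGraph()
        g.add_node("c", "concept")
        g.add_node("r", "recipe")
        with pytest.raises(GraphSchemaError):
            g.add_edge("c", "contains_ingredient", "r")

    def test_self_loops_rejected(self):
        g = FoodGraph()
        g.add_node("c", "concept")
        with pytest.raises(GraphSchemaError, match="self-loop"):
            g.add_edge("c", "promotes", "c")

    def test_tsv_roundtrip(self, tmp_path):
        g = chain_graph()
        p = tmp_path / "graph.tsv"
        write_graph(g, p)
        assert read_graph(p) == g


class TestConceptMapping:
    def test_immune_query_maps_to_concept(self):
        g = chain_graph()
        out = map_query_to_concepts("Immune boosting dinner", DEFAULT_CONCEPT_LEXICON, g)
        assert out == frozenset({"immune_system"})

    def test_dish_query_maps_to_nothing(self):
        assert map_query_to_concepts("pizza", DEFAULT_CONCEPT_LEXICON) == frozenset()

    def test_matches_equal_bruteforce_substring_scan(self):
        lex = {"alpha goal": "c_alpha", "beta goal": "c_beta", "gamma": "c_gamma"}
        queries = ["alpha goal now", "beta goal and gamma", "nothing here"]
        for q in queries:
            expected = frozenset(
                c for p, c in lex.items() if p in q.lower()
            )
            assert map_query_to_concepts(q, lex) == expected


class TestPathScoring:
    def test_single_hop_weight_is_decay_base(self):
        g = chain_graph()
        paths = enumerate_paths(g, "ginger", "r1", max_len=3)
        assert len(paths) == 1
        assert paths[0].length == 1
        assert paths[0].weight == pytest.approx(0.9)

    def test_two_hop_weight(self):
        g = chain_graph()
        paths = enumerate_paths(g, "anti_inflammatory", "r1", max_len=3)
        assert [p.weight for p in paths] == [pytest.approx(0.81)]

    def test_weight_strictly_decreasing_in_length(self):
        for lam in (0.1, 0.5, 0.9, 0.99):
            ws = [PathScore(tuple(str(i) for i in range(n + 1)), lam).weight
                  for n in range(1, 6)]
            assert all(a > b for a, b in zip(ws, ws[1:]))

    def test_max_len_respected_exactly(self):
        g = chain_graph()
        # immune_system -> r1: length-3 chain and length-2 shortcut
        two = enumerate_paths(g, "immune_system", "r1", max_len=2)
        assert {p.length for p in two} == {2}
        three = enumerate_paths(g, "immune_system", "r1", max_len=3)
        assert sorted(p.length for p in three) == [2, 3]

    def test_graph_score_sums_all_paths(self):
        g = chain_graph()
        # 0.9^2 (shortcut) + 0.9^3 (full chain)
        assert graph_score(g, ["immune_system"], "r1") == pytest.approx(0.81 + 0.729)

    def test_unreachable_recipe_scores_zero(self):
        g = chain_graph()
        g.add_node("r2", "recipe")
        assert graph_score(g, ["immune_system"], "r2") == 0.0

    def test_adding_edge_never_decreases_score(self):
        g = chain_graph()
        g.add_node("garlic", "ingredient")
        g.add_node("r2", "recipe")
        before = graph_score(g, ["immune_system"], "r1")
        g.add_edge("anti_inflammatory", "has_ingredient", "garlic")
        g.add_edge("garlic", "contains_ingredient", "r1")
        after = graph_score(g, ["immune_system"], "r1")
        assert after >= before


def random_typed_graph(rng, n_concepts, n_ingredients, n_recipes, p_edge):
    g = FoodGraph()
    cs = [f"c{i}" for i in range(n_concepts)]
    ings = [f"i{i}" for i in range(n_ingredients)]
    rs = [f"r{i}" for i in range(n_recipes)]
    for c in cs:
        g.add_node(c, "concept")
    for i in ings:
        g.add_node(i, "ingredient")
    for r in rs:
        g.add_node(r, "recipe")
    adj = {}
    for a in cs:
        for b in cs:
            if a != b and rng.random() < p_edge:
                g.add_edge(a, "promotes", b)
                adj.setdefault(a, set()).add(b)
        for b in ings:
            if rng.random() < p_edge:
                g.add_edge(a, "has_ingredient", b)
                adj.setdefault(a, set()).add(b)
    for a in ings:
        for b in rs:
            if rng.random() < p_edge:
                g.add_edge(a, "contains_ingredient", b)
                adj.setdefault(a, set()).add(b)
    return g, adj, cs, rs


class TestEnumerationOracle:
    def test_random_graphs_match_exhaustive_dfs(self):
        """graph_score equals independent DFS path enumeration on random
        typed graphs of up to 25 nodes."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            nc, ni, nr = rng.integers(1, 6), rng.integers(1, 12), rng.integers(1, 8)
            g, adj, cs, rs = random_typed_graph(rng, nc, ni, nr, p_edge=0.3)
            max_len = int(rng.integers(1, 5))
            sources = list(rng.choice(cs, size=min(2, len(cs)), replace=False))
            target = str(rng.choice(rs))
            expected = sum(
                0.9 ** (len(p) - 1)
                for s in sources for p in dfs_paths(adj, s, target, max_len)
            )
            assert graph_score(g, sources, target, max_len) == pytest.approx(expected)


class TestSourcing:
    def test_beta_zero_keeps_hybrid_ordering(self):
        g = chain_graph()
        hybrid = [ScoredCandidate("r1", s_hybrid=0.2)]
        out = source_candidates(hybrid, g, ["immune_system"], beta=0.0, pool_size=10)
        assert [c.recipe_id for c in out] == ["r1"]

    def test_graph_only_recipe_enters_pool(self):
        g = chain_graph()
        out = source_candidates([], g, ["immune_system"], beta=0.3, pool_size=10)
        ids = [c.recipe_id for c in out]
        assert "r1" in ids
        assert out[0].s_graph > 0

    def test_joint_ranking_matches_bruteforce(self, gen_corpus, gen_graph, gen_indexes):
        from mealrank.retrieval import hybrid_retrieve
        sparse, dense = gen_indexes
        hybrid = hybrid_retrieve("hearty dinner", sparse, dense, k=20)
        beta = 0.3
        out = source_candidates(hybrid, gen_graph, ["immune_system"], beta=beta,
                                pool_size=1000)
        joint = {c.recipe_id: (c.s_hybrid or 0) + beta * c.s_graph for c in out}
        ids = [c.recipe_id for c in out]
        assert ids == sorted(joint, key=lambda i: (-joint[i], i))
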