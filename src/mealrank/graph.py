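"""Food knowledge graph expansion with path-decay scoring.

The graph links abstract health concepts to ingredients and ingredients to
the recipes containing them.  A query is mapped to entry concepts; every
simple directed path p from an entry concept to a recipe contributes a
weight w(p) = lambda^len(p) (lambda in (0, 1), default 0.9), and the graph
expansion score of a recipe is the sum of path weights:

    s_graph(q, r) = sum over paths p from V_q to r of lambda^len(p)

Only simple paths (no repeated nodes) are counted — the sum would diverge
on cycles otherwise — and traversal depth is bounded (default 3 edges:
concept -> concept -> ingredient -> recipe).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .corpus import normalize_ingredient
from .retrieval import ScoredCandidate

NODE_TYPES = ("concept", "ingredient", "recipe")
# edge type -> allowed (source type, target type) pairs
EDGE_TYPES: dict[str, tuple[tuple[str, str], ...]] = {
    "promotes": (("concept", "concept"), ("concept", "ingredient")),
    "has_ingredient": (("concept", "ingredient"),),
    "contains_ingredient": (("ingredient", "recipe"),),
}

DEFAULT_LAMBDA = 0.9
DEFAULT_MAX_HOPS = 3


class GraphSchemaError(ValueError):
    pass


class FoodGraph:
    """Typed directed graph over concept, ingredient and recipe nodes."""

    def __init__(self):
        self.g = nx.DiGraph()

    def add_node(self, name: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise GraphSchemaError(f"unknown node type {node_type!r}")
        existing = self.g.nodes.get(name)
        if existing is not None and existing["node_type"] != node_type:
            raise GraphSchemaError(
                f"node {name!r} already typed {existing['node_type']!r}"
            )
        self.g.add_node(name, node_type=node_type)

    def add_edge(self, source: str, edge_type: str, target: str) -> None:
        if source == target:
            raise GraphSchemaError(f"self-loop on {source!r}")
        if edge_type not in EDGE_TYPES:
            raise GraphSchemaError(f"unknown edge type {edge_type!r}")
        for node in (source, target):
            if node not in self.g:
                raise GraphSchemaError(f"unknown node {node!r}; declare it first")
        pair = (self.g.nodes[source]["node_type"], self.g.nodes[target]["node_type"])
        if pair not in EDGE_TYPES[edge_type]:
            raise GraphSchemaError(
                f"edge {edge_type!r} cannot connect {pair[0]} -> {pair[1]}"
            )
        self.g.add_edge(source, target, edge_type=edge_type)

    def node_type(self, name: str) -> str:
        return self.g.nodes[name]["node_type"]

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["node_type"] == node_type]

    def __contains__(self, name: str) -> bool:
        return name in self.g

    def __eq__(self, other) -> bool:
        if not isinstance(other, FoodGraph):
            return NotImplemented
        return (
            dict(self.g.nodes(data=True)) == dict(other.g.nodes(data=True))
            and dict(self.g.edges) == dict(other.g.edges)
            and all(self.g.edges[e] == other.g.edges[e] for e in self.g.edges)
        )


@dataclass(frozen=True)
class PathScore:
    path: tuple[str, ...]
    decay: float = DEFAULT_LAMBDA

    @property
    def length(self) -> int:
        return len(self.path) - 1

    @property
    def weight(self) -> float:
        return self.decay ** self.length


def map_query_to_concepts(
    q: str, concept_lexicon: dict[str, str], graph: Optional[FoodGraph] = None
) -> frozenset[str]:
    """Map a query to graph entry concepts via a phrase -> concept lexicon.

    Matching is case-insensitive substring scan with hyphens collapsed;
    concepts absent from the graph (when one is given) are dropped.
    """
    qn = " " + q.lower().replace("-", " ").replace("_", " ") + " "
    hits = set()
    for phrase, concept in concept_lexicon.items():
        p = phrase.lower().replace("-", " ").replace("_", " ")
        if p in qn:
            hits.add(concept)
    if graph is not None:
        hits = {c for c in hits if c in graph and graph.node_type(c) == "concept"}
    return frozenset(hits)


def enumerate_paths(
    graph: FoodGraph,
    source: str,
    target: str,
    max_len: int = DEFAULT_MAX_HOPS,
    decay: float = DEFAULT_LAMBDA,
) -> list[PathScore]:
    """All simple directed paths source -> target with at most max_len edges."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must lie in (0, 1)")
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"unknown node {node!r}")
    paths = nx.all_simple_paths(graph.g, source, target, cutoff=max_len)
    return [PathScore(tuple(p), decay) for p in paths]


def graph_score(
    graph: FoodGraph,
    concepts: Iterable[str],
    recipe_id: str,
    max_len: int = DEFAULT_MAX_HOPS,
    decay: float = DEFAULT_LAMBDA,
) -> float:
    """Sum of decayed path weights from every entry concept to the recipe."""
    if recipe_id not in graph:
        return 0.0
    total = 0.0
    for c in concepts:
        if c not in graph:
            continue
        total += sum(p.weight for p in enumerate_paths(graph, c, recipe_id, max_len, decay))
    return total


def reachable_recipes(
    graph: FoodGraph, concepts: Iterable[str], max_len: int = DEFAULT_MAX_HOPS
) -> set[str]:
    out: set[str] = set()
    for c in concepts:
        if c not in graph:
            continue
        lengths = nx.single_source_shortest_path_length(graph.g, c, cutoff=max_len)
        out.update(n for n in lengths if graph.node_type(n) == "recipe")
    return out


def source_candidates(
    hybrid_list: list[ScoredCandidate],
    graph: FoodGraph,
    concepts: Iterable[str],
    beta: float = 0.3,
    pool_size: int = 200,
    max_len: int = DEFAULT_MAX_HOPS,
    decay: float = DEFAULT_LAMBDA,
) -> list[ScoredCandidate]:
    """Merge hybrid and graph-expanded candidates by the joint signal
    s_hybrid + beta * s_graph, truncated to pool_size.

    Graph-reachable recipes missing from the hybrid list enter the pool with
    s_hybrid = 0, so purely conceptual matches are never lost.
    """
    concepts = list(concepts)
    by_id = {c.recipe_id: c for c in hybrid_list}
    for rid in sorted(reachable_recipes(graph, concepts, max_len)):
        if rid not in by_id:
            by_id[rid] = ScoredCandidate(recipe_id=rid, s_hybrid=0.0)
    for cand in by_id.values():
        cand.s_graph = graph_score(graph, concepts, cand.recipe_id, max_len, decay)
    ranked = sorted(
        by_id.values(),
        key=lambda c: (-((c.s_hybrid or 0.0) + beta * c.s_graph), c.recipe_id),
    )
    return ranked[:pool_size]


# ---------------------------------------------------------------------------
# TSV edge-list serialization
# ---------------------------------------------------------------------------

def write_graph(graph: FoodGraph, path) -> None:
    """Write node declarations (#node lines) followed by typed edges."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#node\tname\ttype\n")
        for name in sorted(graph.g.nodes):
            fh.write(f"#node\t{name}\t{graph.node_type(name)}\n")
        fh.write("#source\tedge_type\ttarget\n")
        for u, v in sorted(graph.g.edges):
            fh.write(f"{u}\t{graph.g.edges[u, v]['edge_type']}\t{v}\n")


def read_graph(path) -> FoodGraph:
    graph = FoodGraph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#source"):
                continue
            if line.startswith("#node"):
                parts = line.split("\t")
                if len(parts) == 3 and parts[1] != "name":
                    graph.add_node(parts[1], parts[2])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphSchemaError(f"line {lineno}: expected 3 tab-separated fields")
            graph.add_edge(parts[0], parts[1], parts[2])
    return graph


def build_graph_from_schema(
    corpus, concepts: Optional[dict[str, tuple[tuple[str, ...], tuple[str, ...]]]] = None
) -> FoodGraph:
    """Build a FoodGraph from the built-in concept schema plus a corpus's
    ingredient -> recipe containment edges."""
    from .lexicons import CONCEPTS

    schema = concepts if concepts is not None else CONCEPTS
    graph = FoodGraph()
    for c in schema:
        graph.add_node(c, "concept")
    ingredient_nodes: set[str] = set()
    for c, (sub_concepts, ings) in schema.items():
        for ing in ings:
            ing = normalize_ingredient(ing)
            if ing not in ingredient_nodes:
                graph.add_node(ing, "ingredient")
                ingredient_nodes.add(ing)
        for sc in sub_concepts:
            graph.add_edge(c, "promotes", sc)
        for ing in ings:
            graph.add_edge(c, "has_ingredient", normalize_ingredient(ing))
    for r in corpus:
        graph.add_node(r.id, "recipe")
        for ing in r.ingredients:
            if ing in ingredient_nodes:
                graph.add_edge(ing, "contains_ingredient", r.id)
    return graph
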