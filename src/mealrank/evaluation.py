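"""Ranking metrics and the ablation harness.

Metrics follow standard IR definitions: Recall@k (|top-k ∩ relevant| /
|relevant|), Semantic Recall@k as hit-rate (1 if any relevant item is in
the top-k), NDCG@k with a log2(rank+1) discount, and CS-Rate — the percent
of recommended items whose recipes satisfy every ground-truth hard
constraint, checked against the benchmark's planted constraints rather
than whatever the intent parser produced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .corpus import ConstraintSet, RecipeCorpus
from .graph import FoodGraph
from .pipeline import RankingConfig, recommend
from .rerank import IngredientOntology, check_constraints
from .retrieval import DenseIndex, SparseIndex
from .synth import BenchmarkQuery


def recall_at_k(ranked_ids: Sequence[str], relevant_ids: set[str] | frozenset[str], k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant_ids:
        raise ValueError("empty relevant set; exclude this query from averaging")
    top = set(ranked_ids[:k])
    return len(top & set(relevant_ids)) / len(relevant_ids)


def semantic_recall_at_k(
    ranked_ids: Sequence[str], relevant_ids: set[str] | frozenset[str], k: int
) -> float:
    """Hit-rate variant: 1 if the top-k contains at least one relevant id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not relevant_ids:
        raise ValueError("empty relevant set; exclude this query from averaging")
    return 1.0 if set(ranked_ids[:k]) & set(relevant_ids) else 0.0


def ndcg_at_k(ranked_ids: Sequence[str], grades: Mapping[str, float], k: int) -> float:
    if k < 1:
        raise ValueError("k must be >= 1")
    if any(g < 0 for g in grades.values()):
        raise ValueError("grades must be >= 0")
    dcg = sum(
        grades.get(rid, 0.0) / math.log2(rank + 1)
        for rank, rid in enumerate(ranked_ids[:k], start=1)
    )
    ideal = sorted(grades.values(), reverse=True)[:k]
    idcg = sum(g / math.log2(rank + 1) for rank, g in enumerate(ideal, start=1))
    return dcg / idcg if idcg > 0 else 0.0


def cs_rate(
    results_per_query: Sequence[Sequence[str]],
    constraints_per_query: Sequence[ConstraintSet],
    corpus: RecipeCorpus,
    k: int = 5,
    ontology: Optional[IngredientOntology] = None,
) -> float:
    """Percent of recommended items (micro-averaged over the top-k of every
    query) satisfying all ground-truth hard constraints.  An empty result
    list counts as 0 satisfied out of k for that query."""
    ontology = ontology if ontology is not None else IngredientOntology.default()
    satisfied = 0
    total = 0
    for ranked, cons in zip(results_per_query, constraints_per_query):
        top = list(ranked[:k])
        if not top:
            total += k
            continue
        total += len(top)
        for rid in top:
            if check_constraints(corpus[rid], cons, ontology).passed:
                satisfied += 1
    return 100.0 * satisfied / total if total else 100.0


@dataclass
class EvalReport:
    variant: str
    per_query: dict[str, list[float]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_query[metric]))

    def std(self, metric: str) -> float:
        return float(np.std(self.per_query[metric]))

    def summary(self) -> dict:
        return {
            "variant": self.variant,
            "config": self.config,
            "metrics": {
                m: {"mean": self.mean(m), "std": self.std(m), "n": len(v)}
                for m, v in self.per_query.items()
            },
        }


ABLATION_VARIANTS = ("full", "no_graph", "fixed_alpha", "no_cross_encoder")


def _variant_config(variant: str, base: RankingConfig) -> RankingConfig:
    kw = dict(
        beta=base.beta, gamma=base.gamma, pool_size=base.pool_size,
        top_k=base.top_k, mode=base.mode, decay=base.decay,
        max_hops=base.max_hops, use_graph=base.use_graph,
        use_cross=base.use_cross, fixed_alpha=base.fixed_alpha,
    )
    if variant == "full":
        pass
    elif variant == "no_graph":
        kw["use_graph"] = False
    elif variant == "fixed_alpha":
        kw["fixed_alpha"] = 0.7
    elif variant == "no_cross_encoder":
        kw["use_cross"] = False
    else:
        raise ValueError(f"unknown ablation variant {variant!r}")
    return RankingConfig(**kw)


def evaluate_benchmark(
    benchmark: Sequence[BenchmarkQuery],
    corpus: RecipeCorpus,
    graph: Optional[FoodGraph],
    sparse: SparseIndex,
    dense: DenseIndex,
    cfg: RankingConfig = RankingConfig(),
    k: int = 5,
    ontology: Optional[IngredientOntology] = None,
    variant: str = "full",
) -> EvalReport:
    """Run the pipeline over a benchmark and compute all metrics.

    The pipeline parses each query itself; CS-Rate is nevertheless checked
    against the benchmark's ground-truth constraints.
    """
    report = EvalReport(variant=variant, config={
        "k": k, "beta": cfg.beta, "gamma": cfg.gamma, "pool_size": cfg.pool_size,
        "mode": cfg.mode, "use_graph": cfg.use_graph, "use_cross": cfg.use_cross,
        "fixed_alpha": cfg.fixed_alpha,
    })
    results, constraints = [], []
    for bq in benchmark:
        res = recommend(bq.query, corpus, graph, sparse, dense, cfg, ontology=ontology)
        ids = res.top_ids()
        results.append(ids)
        constraints.append(bq.constraints)
        grades = {rid: 1.0 for rid in bq.relevant_ids}
        report.per_query.setdefault("recall_at_k", []).append(
            recall_at_k(ids, bq.relevant_ids, k))
        report.per_query.setdefault("semantic_recall_at_k", []).append(
            semantic_recall_at_k(ids, bq.relevant_ids, k))
        report.per_query.setdefault("ndcg_at_k", []).append(
            ndcg_at_k(ids, grades, k))
    rate = cs_rate(results, constraints, corpus, k, ontology)
    report.per_query["cs_rate"] = [rate]
    return report


def run_ablation(
    benchmark: Sequence[BenchmarkQuery],
    corpus: RecipeCorpus,
    graph: FoodGraph,
    sparse: SparseIndex,
    dense: DenseIndex,
    variants: Sequence[str] = ABLATION_VARIANTS,
    base_cfg: RankingConfig = RankingConfig(),
    k: int = 5,
) -> dict[str, EvalReport]:
    """Evaluate the same benchmark under each ablation variant."""
    out: dict[str, EvalReport] = {}
    for variant in variants:
        cfg = _variant_config(variant, base_cfg)
        out[variant] = evaluate_benchmark(
            benchmark, corpus, graph, sparse, dense, cfg, k, variant=variant
        )
    return out
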