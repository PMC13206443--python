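"""Run configuration: YAML/JSON loading with validated defaults.

Defaults are the engine's standard operating point: the adaptive alpha
table {ingredient_list: 0.35, dish_name: 0.20, intent_marker: 0.65,
default: 0.50}, path decay 0.9 over at most 3 hops, nutrition weights
(0.5, 0.3, 0.2), candidate pool 200 and top-5 output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .nutrition import NutritionConfig, RDATable
from .pipeline import RankingConfig
from .retrieval import AlphaPolicy, QueryClass

log = logging.getLogger("mealrank")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    corpus_path: Optional[str] = None
    graph_path: Optional[str] = None
    ontology_path: Optional[str] = None
    rda_path: Optional[str] = None
    alpha_policy: AlphaPolicy = field(default_factory=AlphaPolicy)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    nutrition: NutritionConfig = field(default_factory=NutritionConfig)
    rda: RDATable = field(default_factory=RDATable)
    k1: float = 1.5
    b: float = 0.75
    embed_dim: int = 256
    seed: int = 0

    def echo(self) -> dict:
        return {
            "paths": {
                "corpus": self.corpus_path, "graph": self.graph_path,
                "ontology": self.ontology_path, "rda": self.rda_path,
            },
            "alpha": {c.value: a for c, a in self.alpha_policy.table.items()},
            "ranking": {
                "beta": self.ranking.beta, "gamma": self.ranking.gamma,
                "pool_size": self.ranking.pool_size, "top_k": self.ranking.top_k,
                "mode": self.ranking.mode, "lambda": self.ranking.decay,
                "max_hops": self.ranking.max_hops,
            },
            "nutrition": {
                "weights": list(self.nutrition.weights),
                "target_ratios": list(self.nutrition.target_ratios),
                "tau": self.nutrition.tau, "kappa": self.nutrition.kappa,
                "meals_per_day": self.nutrition.meals_per_day,
            },
            "bm25": {"k1": self.k1, "b": self.b},
            "embed_dim": self.embed_dim,
            "seed": self.seed,
        }


def _build(data: dict) -> RunConfig:
    try:
        alpha_tbl = dict(AlphaPolicy().table)
        for name, val in (data.get("alpha") or {}).items():
            alpha_tbl[QueryClass(name)] = float(val)
        rk = data.get("ranking") or {}
        ranking = RankingConfig(
            beta=rk.get("beta", 0.3), gamma=rk.get("gamma", 0.2),
            pool_size=rk.get("pool_size", 200), top_k=rk.get("top_k", 5),
            mode=rk.get("mode", "fast"), decay=rk.get("lambda", 0.9),
            max_hops=rk.get("max_hops", 3),
        )
        nu = data.get("nutrition") or {}
        nutrition = NutritionConfig(
            target_ratios=tuple(nu.get("target_ratios", (0.30, 0.40, 0.30))),
            tau=nu.get("tau", 1.5), kappa=nu.get("kappa", 1.0),
            weights=tuple(nu.get("weights", (0.5, 0.3, 0.2))),
            meals_per_day=nu.get("meals_per_day", 3),
        )
        rda = RDATable(dict(data["rda"])) if "rda" in data and isinstance(data["rda"], dict) else RDATable()
        cfg = RunConfig(
            corpus_path=data.get("corpus"), graph_path=data.get("graph"),
            ontology_path=data.get("ontology"),
            rda_path=data.get("rda") if isinstance(data.get("rda"), str) else None,
            alpha_policy=AlphaPolicy(alpha_tbl), ranking=ranking,
            nutrition=nutrition, rda=rda,
            k1=data.get("k1", 1.5), b=data.get("b", 0.75),
            embed_dim=data.get("embed_dim", 256), seed=data.get("seed", 0),
        )
    except (ValueError, KeyError) as exc:
        raise ConfigError(str(exc)) from exc
    for name, p in (("corpus", cfg.corpus_path), ("graph", cfg.graph_path),
                    ("ontology", cfg.ontology_path), ("rda", cfg.rda_path)):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{name} path does not exist: {p}")
    if cfg.rda_path:
        cfg.rda = RDATable.from_yaml(cfg.rda_path)
    log.info("resolved config: %s", json.dumps(cfg.echo()))
    return cfg


def load_config(path=None) -> RunConfig:
    """Load a YAML/JSON run config; absent keys get validated defaults."""
    if path is None:
        return _build({})
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _build(data)
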