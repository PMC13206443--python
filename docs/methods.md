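# Methods

This note documents the models and procedures implemented in `mealrank`,
the defaults that matter, and what the synthetic study conditions do and do
not show.

## Problem setting

A user issues a fuzzy dietary query ("something light but filling for
dinner"). The engine must (i) translate it into structured constraints,
(ii) retrieve candidate recipes from a corpus where each recipe carries a
5-dimensional nutrient vector (calories, protein, fat, carbohydrates,
fiber), normalized ingredients, course and total mass, (iii) deterministically
veto anything that violates a hard constraint (allergen, diet, course,
macro bound), (iv) score nutritional suitability, and (v) rank.

## Stage 1 — intent refinement

The primary parser is a phrase lexicon: each matched phrase contributes a
partial constraint set, and fragments are merged. Conflicting macronutrient
bounds intersect, so the *tighter* bound always wins — a safety-first
choice. The shipped lexicon covers satiety markers ("light" → ≤600 kcal,
"filling" → ≥20 g protein), courses, health goals, diets, and common
allergen phrasings. A semantic fallback maps the query embedding onto
precomputed intent centroids by cosine similarity (ties broken by centroid
name; similarity below 0.3 yields no constraints — the threshold is chosen
to avoid spurious matches with the lexical hash embedder, where unrelated
texts typically score near 0). An external language model can be plugged in
behind the same `query -> ConstraintSet` contract; the deterministic parser
is the default because it is reproducible and auditable.

## Stage 2 — adaptive hybrid retrieval

The hybrid score is `alpha * s_dense + (1 - alpha) * s_bm25` with alpha
chosen by a rule-based query-shape classifier:

| query class | rule | alpha |
|---|---|---|
| ingredient list | ≥ 2 comma-separated food phrases | 0.35 |
| short dish name | ≤ 2 tokens, all dish/food words | 0.20 |
| intent marker | contains a lexicon intent/health phrase | 0.65 |
| default | anything else | 0.50 |

Priority order is ingredient list > intent marker > dish name, so
"healthy pizza" is treated as intent-rich.

BM25 is Okapi with k1 = 1.5, b = 0.75 (conventional settings). The IDF
uses the non-negative `ln(1 + (N - df + 0.5)/(df + 0.5))` smoothing so the
sparse score is 0 exactly when no query term occurs in the document.
Because raw BM25 is unbounded while cosine similarity lives in [-1, 1],
both components are min-max normalized over the pooled candidates before
mixing; a constant pool normalizes to zeros. Ties always break by ascending
recipe id.

The default dense encoder is a deterministic, keyed-hash bag of word and
character-trigram features (dimension 256, L2-normalized). It captures
lexical and sub-word overlap only — not distributional semantics — which is
exactly why graph expansion carries the weight for abstract health intents
in the synthetic experiments. Any sentence encoder can be substituted
through the `embed(text)` interface.

## Stage 2b — knowledge-graph expansion

The food graph types its nodes (concept, ingredient, recipe) and edges
(`promotes`: concept→concept/ingredient, `has_ingredient`:
concept→ingredient, `contains_ingredient`: ingredient→recipe). A query is
mapped to entry concepts by phrase lookup plus any health goals extracted
in Stage 1. Every *simple* directed path p from an entry concept to a
recipe contributes `w(p) = lambda^len(p)` with lambda = 0.9; the recipe's
expansion score is the sum over paths. Simple paths only, because the sum
diverges on cycles. Traversal depth is bounded at 3 edges: the canonical
bridge is concept → ingredient → recipe (2 edges), but concept → concept →
ingredient → recipe chains (e.g. immune support → anti-inflammatory →
turmeric → recipe) need a third hop. Candidates are pooled by the joint
signal `s_hybrid + beta * s_graph` (beta = 0.3 by default), and every
graph-reachable recipe enters the pool even when hybrid retrieval missed
it — that is the mechanism that rescues abstract intents.

## Stage 3 — reranking and hard filtering

The cross-scorer slot is pluggable; the shipped default scores the fraction
of query-side terms (content tokens plus concrete food terms implied by
matched intent phrases) present in the recipe text, in [0, 1]. It replaces
the hybrid score for final ranking.

Hard filtering is a deterministic veto with category-aware exclusion:
an excluded name matches an ingredient exactly, through ontology category
expansion ("nuts" → peanut, almond, ...), or as a word inside a compound
name ("peanut" matches "peanut butter"). Mandatory inclusions, course,
per-meal macro bounds, and diet-tag rules (vegan forbids all animal
categories, etc., shipped as editable config) are checked the same way, and
every violation is recorded in a JSON-serializable verdict for audit.
Unknown exclusion names fall back to literal ingredient matching. Macro
bounds apply to per-recipe (= per-meal) nutrient values.

## Nutrition model

Per-meal targets divide daily reference values by 3 (meals per day). The
shipped general-adult table (2000 kcal, 50 g protein, 70 g fat, 260 g
carbohydrate, 28 g fiber) is an editable config, not a clinical model.

* Adequacy `A_m = min(1, n_m / T_m)` — capped so moderate excess is not
  penalized; `A_abs` averages over all five nutrient dimensions (calories
  included; the modeled set is configurable).
* Energy ratios use Atwater factors 4/4/9 kcal/g; the denominator is the
  macro-derived energy rather than the stored calories field, so ratios
  always sum to 1 even when a label disagrees with its macros. Balance is
  `mean(1 - |R_i - target_i|)` against 30/40/30 protein/carb/fat. Fiber
  contributes to adequacy but not to energy ratios.
* Energy density ED = kcal/g is a satiety proxy: score 1 up to
  tau = 1.5 kcal/g (the conventional low/medium energy-density boundary),
  then `exp(-kappa (ED - tau))` with kappa = 1 (one e-fold per kcal/g).
  Continuous at the threshold.
* Composite: `0.5 * A_abs + 0.3 * A_ratio + 0.2 * A_ED`.

A recipe with all macros zero gets ratio-balance 0 rather than an error, so
degenerate records never crash a ranking pass.

## Final ranking and the critic

`Phi = s_cross + beta * s_graph + gamma * S_nutrition` with beta = 0.3 and
gamma = 0.2, chosen so the semantic interaction score dominates and the
graph/nutrition terms act as boosts. Candidates are sorted by Phi
(ties by id). In strict mode a rule-based critic re-verifies candidates in
rank order until the top-k is filled: it re-runs every hard-constraint
check and additionally scans title and preparation-step text for excluded
terms that never appear in the ingredient list ("garnish with crushed
peanuts") and for beverage language conflicting with a main-course
constraint. Failed candidates are removed and the next-ranked survivors
promoted; the critic can only remove violations, never add them. An
external language-model reviewer can replace it behind the same verdict
contract. Every run emits a full audit record (constraints, alpha, stage
counts, score breakdowns, verdicts, and — on an empty result — the binding
constraints).

## Synthetic study conditions

The generator emulates the structure of a fuzzy-intent benchmark:

* **Corpus** — themed recipes cycling through health-goal, taste, occasion
  and filler templates across the five courses; nutrient vectors are drawn
  per course with calories consistent with Atwater energy of the drawn
  macros; masses 150–600 g. Health-goal recipes carry concept-promoted
  ingredients and are clamped to satisfy the goal's macro fragment.
* **Violators** — a configurable fraction (default 20%) of recipes are
  planted violators: allergen carriers, course-mismatched lookalikes (a
  beverage titled after a health goal), and hidden violators whose
  ingredient list is clean but whose steps mention an excluded item. Ids
  and kinds are kept in corpus annotations.
* **Benchmark** — queries stratified 30/26/24/20 percent over health-goal,
  taste/craving, occasion/context and hybrid/complex categories
  (largest-remainder rounding, so 150 queries split 45/39/36/30).
  Ground-truth constraints are the lexicon parse of the query; relevance
  pools (3–8 recipes) contain only constraint-satisfying recipes carrying
  the query's signature terms. Health-goal relevance is planted through
  graph concepts only — the recipes never contain the abstract goal phrase
  — so lexical retrieval cannot resolve those queries and the ablation
  direction (full > no-graph) is a property of the mechanism, not of
  lexical leakage.

What passing these conditions does *not* show: performance on real recipe
text (paraphrase, misspellings, multilingual names), real nutrient
databases, or human relevance judgments. The synthetic corpus is
deliberately easy for the constraint machinery (ingredients are drawn from
the same vocabulary the ontology covers) — it validates mechanism
correctness, not field accuracy.

## Evaluation choices

* Semantic Recall@k is the hit-rate variant (1 if any relevant item is in
  the top-k). Recall@k is the standard set-overlap fraction. NDCG@k uses
  the log2(rank+1) discount with binary grades by default.
* CS-Rate is micro-averaged over the top-5 recommended items and checked
  against the benchmark's ground-truth constraints, not against whatever
  the intent parser produced; an empty result counts 0 of k.
* The ablation harness re-runs the identical benchmark with one component
  removed: `no_graph` disables expansion, `fixed_alpha` pins alpha = 0.7,
  `no_cross_encoder` ranks by the hybrid score.

Problem sizes in the shipped tests: corpora of 100–600 recipes, benchmarks
of 24–150 queries, 1000 random graphs of ≤ 25 nodes for the path-scoring
oracle — sizes at which every ranking can also be recomputed by brute
force, which is what the oracle tests do.

## Known limitations

* Ingredient normalization is a naive singularizer; it is deterministic but
  not linguistically complete ("leaves" → "leafe" style errors are possible
  outside the built-in vocabulary).
* The hash embedder has no semantics; with a real encoder the adaptive
  alpha trade-off would look different.
* Diet rules are binary ingredient exclusions; sourcing and
  cross-contamination reasoning (Halal/Kosher) are out of scope.
* The nutrition model is a population-level heuristic (equal per-meal RDA
  split); it is explicitly not individualized dietary advice.
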