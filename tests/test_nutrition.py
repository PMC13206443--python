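"""Closed-form checks and invariants of the nutrition scoring model."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mealrank.corpus import NutrientVector
from mealrank.nutrition import (
    NutritionConfig, NutritionConfigError, RDATable, adequacy,
    aggregate_adequacy, composite_score, energy_density_score, energy_ratios,
    ratio_balance, score_recipe,
)

from conftest import make_recipe

CFG = NutritionConfig()


class TestAdequacy:
    def test_at_target_is_one(self):
        assert adequacy(n_m=2000 / 3, rda_m=2000, meals_per_day=3) == 1.0

    def test_capped_at_one_for_excess(self):
        assert adequacy(n_m=2 * 2000 / 3, rda_m=2000) == 1.0

    def test_zero_amount_is_zero(self):
        assert adequacy(0.0, 50.0) == 0.0

    def test_negative_amount_raises(self):
        with pytest.raises(ValueError):
            adequacy(-1.0, 50.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 500), st.floats(0, 500), st.floats(1, 5000))
    def test_monotone_in_amount(self, a, b, rda):
        lo, hi = sorted((a, b))
        assert adequacy(lo, rda) <= adequacy(hi, rda)

    def test_aggregate_is_mean(self):
        assert aggregate_adequacy({"a": 1.0, "b": 0.0}) == 0.5
        per = {"a": 0.2, "b": 0.4, "c": 0.6, "d": 0.8, "e": 1.0}
        assert aggregate_adequacy(per) == pytest.approx(sum(per.values()) / 5)

    def test_empty_nutrient_set_rejected(self):
        with pytest.raises(NutritionConfigError):
            aggregate_adequacy({})


class TestEnergyRatios:
    def test_balanced_macros_hit_targets(self):
        # 4*30 = 120 kcal protein, 4*40 = 160 carb, 9*13.333 = 120 fat
        n = NutrientVector(calories=400, protein=30, fat=40 / 3, carbohydrates=40, fiber=0)
        r = energy_ratios(n, CFG)
        assert r == pytest.approx((0.30, 0.40, 0.30), abs=1e-9)

    def test_only_protein_gives_unit_share(self):
        n = NutrientVector(calories=100, protein=10, fat=0, carbohydrates=0, fiber=0)
        assert energy_ratios(n, CFG) == (1.0, 0.0, 0.0)

    def test_all_macros_zero_raises(self):
        n = NutrientVector(calories=100, protein=0, fat=0, carbohydrates=0, fiber=0)
        with pytest.raises(ValueError):
            energy_ratios(n, CFG)

    @settings(max_examples=60, deadline=None)
    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100))
    def test_ratios_sum_to_one_and_match_direct_formula(self, p, c, f):
        n = NutrientVector(calories=1, protein=p, fat=f, carbohydrates=c, fiber=0)
        rp, rc, rf = energy_ratios(n, CFG)
        assert rp + rc + rf == pytest.approx(1.0)
        tot = 4 * p + 4 * c + 9 * f
        assert (rp, rc, rf) == pytest.approx((4 * p / tot, 4 * c / tot, 9 * f / tot))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(0.1, 50),
           st.floats(0.5, 4.0))
    def test_scaling_leaves_ratios_unchanged(self, p, c, f, s):
        n1 = NutrientVector(calories=1, protein=p, fat=f, carbohydrates=c, fiber=0)
        n2 = NutrientVector(calories=s, protein=s * p, fat=s * f,
                            carbohydrates=s * c, fiber=0)
        assert energy_ratios(n1, CFG) == pytest.approx(energy_ratios(n2, CFG))


class TestRatioBalance:
    def test_exact_targets_score_one(self):
        assert ratio_balance((0.30, 0.40, 0.30), CFG) == pytest.approx(1.0)

    def test_all_protein_direct_evaluation(self):
        # (1-|1-0.3|) + (1-|0-0.4|) + (1-|0-0.3|) = 0.3 + 0.6 + 0.7
        assert ratio_balance((1.0, 0.0, 0.0), CFG) == pytest.approx((0.3 + 0.6 + 0.7) / 3)

    def test_uniform_thirds_direct_evaluation(self):
        r = 1 / 3
        expected = ((1 - abs(r - 0.3)) + (1 - abs(r - 0.4)) + (1 - abs(r - 0.3))) / 3
        assert ratio_balance((r, r, r), CFG) == pytest.approx(expected)


class TestEnergyDensity:
    def test_at_threshold_scores_one(self):
        ed, a = energy_density_score(calories=150, mass_g=100, cfg=CFG)  # ED = tau
        assert ed == pytest.approx(CFG.tau)
        assert a == 1.0

    def test_below_threshold_scores_one(self):
        _, a = energy_density_score(100, 100, CFG)
        assert a == 1.0

    def test_one_over_kappa_above_threshold_gives_inverse_e(self):
        ed_target = CFG.tau + 1.0 / CFG.kappa
        _, a = energy_density_score(ed_target * 100, 100, CFG)
        assert a == pytest.approx(math.exp(-1))

    def test_continuous_at_threshold(self):
        eps = 1e-9
        _, below = energy_density_score((CFG.tau - eps) * 100, 100, CFG)
        _, above = energy_density_score((CFG.tau + eps) * 100, 100, CFG)
        assert below == pytest.approx(above, abs=1e-6)

    def test_nonpositive_mass_raises(self):
        with pytest.raises(ValueError):
            energy_density_score(100, 0, CFG)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0, 2000), st.floats(0, 2000))
    def test_monotone_nonincreasing_in_density(self, c1, c2):
        lo, hi = sorted((c1, c2))
        _, a_lo = energy_density_score(lo, 100, CFG)
        _, a_hi = energy_density_score(hi, 100, CFG)
        assert a_hi <= a_lo


class TestComposite:
    def test_perfect_components_score_one(self):
        assert composite_score(1, 1, 1, CFG) == pytest.approx(1.0)

    def test_adequacy_only_scores_first_weight(self):
        assert composite_score(1, 0, 0, CFG) == pytest.approx(0.5)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_equals_direct_weighted_sum_and_bounded(self, a, b, c):
        got = composite_score(a, b, c, CFG)
        assert got == pytest.approx(0.5 * a + 0.3 * b + 0.2 * c)
        assert 0.0 <= got <= 1.0

    def test_weights_must_sum_to_one(self):
        with pytest.raises(NutritionConfigError):
            NutritionConfig(weights=(0.5, 0.3, 0.1))


class TestScoreRecipe:
    def test_breakdown_components_in_unit_interval(self, gen_corpus):
        rda = RDATable()
        for r in list(gen_corpus)[:40]:
            b = score_recipe(r, rda, CFG)
            for v in (*b.per_nutrient.values(), b.a_abs, b.a_ratio, b.a_ed,
                      b.s_nutrition):
                assert 0.0 <= v <= 1.0
            assert b.energy_density >= 0

    def test_mass_and_nutrient_scaling_invariance(self):
        r1 = make_recipe("s1", mass=200, calories=400, protein=20, fat=10,
                         carbohydrates=50, fiber=4)
        r2 = make_recipe("s2", mass=400, calories=800, protein=40, fat=20,
                         carbohydrates=100, fiber=8)
        b1, b2 = score_recipe(r1), score_recipe(r2)
        assert b1.energy_density == pytest.approx(b2.energy_density)
        assert b1.ratios == pytest.approx(b2.ratios)
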