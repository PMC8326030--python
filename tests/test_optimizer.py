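"""Pathway optimizer: scale factors, substitution pools, deviation LP."""

import numpy as np
import pandas as pd
import pytest

import fiveaday as fa
from conftest import make_foods


def toy_instance(meat_intake=20.0, meat_energy=2.5):
    """1 fruit + 1 veg + 1 sweet + 1 meat + 2 free foods."""
    return make_foods([
        {"id": "fr", "category": "fruit", "baseline_intake_g": 100,
         "energy_density_kcal_per_g": 0.5},
        {"id": "vg", "category": "vegetable", "baseline_intake_g": 100,
         "energy_density_kcal_per_g": 0.4},
        {"id": "sw", "category": "sweet_snack", "baseline_intake_g": 50,
         "energy_density_kcal_per_g": 4.0},
        {"id": "mt", "category": "red_meat", "baseline_intake_g": meat_intake,
         "energy_density_kcal_per_g": meat_energy},
        {"id": "o1", "category": "other", "baseline_intake_g": 200,
         "energy_density_kcal_per_g": 1.5},
        {"id": "o2", "category": "other", "baseline_intake_g": 100,
         "energy_density_kcal_per_g": 2.0},
    ])


class TestEligibleSet:
    def test_fv_all_takes_every_counting_group(self, foods):
        ids = fa.eligible_set(foods, fa.PATHWAYS["FV_ALL"])
        expected = foods[foods["counts_5aday"] & (foods["baseline_intake_g"] > 0)]["id"]
        assert set(ids) == set(expected)

    def test_veg_uk_restricts_to_uk_capable_vegetables(self, foods):
        ids = set(fa.eligible_set(foods, fa.PATHWAYS["VEG_UK"]))
        sel = foods[foods["id"].isin(ids)]
        assert set(sel["category"]) <= {"vegetable", "legume"}
        assert sel["uk_capable"].all() and sel["counts_5aday"].all()

    def test_no_uk_capable_foods_is_infeasible(self):
        foods = make_foods([
            {"id": "fr", "category": "fruit", "baseline_intake_g": 50},
            {"id": "vg", "category": "vegetable", "baseline_intake_g": 50},
        ])
        with pytest.raises(fa.InfeasiblePathwayError, match="no eligible"):
            fa.eligible_set(foods, fa.PATHWAYS["VEG_UK"])

    def test_zero_baseline_foods_stay_frozen(self):
        foods = make_foods([
            {"id": "fr", "category": "fruit", "baseline_intake_g": 50},
            {"id": "fr0", "category": "fruit", "baseline_intake_g": 0.0},
        ])
        assert set(fa.eligible_set(foods, fa.PATHWAYS["FV_ALL"])) == {"fr"}


class TestScaleFactor:
    def test_fv_all_reproduces_printed_pathway_intakes(self, foods, base_diet):
        s = fa.solve_scale_factor(base_diet, foods, fa.PATHWAYS["FV_ALL"])
        assert s == pytest.approx(400.0 / 228.0, abs=1e-9)
        scaled = fa.scaled_diet(base_diet, foods, fa.PATHWAYS["FV_ALL"], s)
        summ = fa.summarize_diet(scaled, foods)
        assert summ.fruit_g == pytest.approx(88 * 400 / 228)  # 154.4 g/d
        assert summ.veg_nonlegume_g + summ.legume_g == pytest.approx(140 * 400 / 228)

    def test_veg_all_scales_vegetables_only(self, foods, base_diet):
        s = fa.solve_scale_factor(base_diet, foods, fa.PATHWAYS["VEG_ALL"])
        scaled = fa.scaled_diet(base_diet, foods, fa.PATHWAYS["VEG_ALL"], s)
        summ = fa.summarize_diet(scaled, foods)
        assert summ.fruit_g == pytest.approx(88.0)
        assert summ.veg_nonlegume_g + summ.legume_g == pytest.approx(312.0)

    def test_already_at_target_returns_identity(self):
        foods = make_foods([
            {"id": "fr", "category": "fruit", "baseline_intake_g": 200},
            {"id": "vg", "category": "vegetable", "baseline_intake_g": 200},
        ])
        assert fa.solve_scale_factor(fa.baseline_diet(foods), foods,
                                     fa.PATHWAYS["FV_ALL"]) == 1.0

    def test_legume_cap_piecewise_solution(self):
        # piece 1 would put legumes at 114 g > 80; the cap pins them and the
        # factor comes from the second linear piece: s = (400-80)/150
        foods = make_foods([
            {"id": "fr", "category": "fruit", "baseline_intake_g": 50},
            {"id": "vg", "category": "vegetable", "baseline_intake_g": 100},
            {"id": "lg", "category": "legume", "baseline_intake_g": 60},
        ])
        diet = fa.baseline_diet(foods)
        s = fa.solve_scale_factor(diet, foods, fa.PATHWAYS["FV_ALL"])
        assert s == pytest.approx(320.0 / 150.0, abs=1e-9)
        scaled = fa.scaled_diet(diet, foods, fa.PATHWAYS["FV_ALL"], s)
        assert fa.count_five_a_day(scaled, foods) == pytest.approx(400.0, abs=1e-9)

    def test_cap_bound_target_unreachable(self):
        # only legumes are eligible, so the count saturates at 30 + 80 < 400
        foods = make_foods([
            {"id": "vg", "category": "vegetable", "baseline_intake_g": 30,
             "uk_capable": False},
            {"id": "lg", "category": "legume", "baseline_intake_g": 40,
             "uk_capable": True},
        ])
        with pytest.raises(fa.InfeasiblePathwayError, match="shortfall"):
            fa.solve_scale_factor(fa.baseline_diet(foods), foods, fa.PATHWAYS["VEG_UK"])


class TestSubstitutionRequirements:
    def test_identity_scaling_needs_no_substitution(self):
        foods = toy_instance()
        diet = fa.baseline_diet(foods)
        assert fa.substitution_requirements(diet, diet, foods) == (0.0, 0.0)

    def test_hand_arithmetic_single_fruit(self):
        foods = make_foods([{"id": "fr", "category": "fruit", "baseline_intake_g": 100,
                             "energy_density_kcal_per_g": 0.6}])
        de_f, de_v = fa.substitution_requirements(
            {"fr": 100.0}, {"fr": 166.0}, foods)
        assert de_f == pytest.approx(39.6)
        assert de_v == 0.0

    def test_fixture_fruit_energy_matches_scaled_increment(self, foods, base_diet):
        spec = fa.PATHWAYS["FV_ALL"]
        s = fa.solve_scale_factor(base_diet, foods, spec)
        scaled = fa.scaled_diet(base_diet, foods, spec, s)
        de_f, de_v = fa.substitution_requirements(base_diet, scaled, foods)
        fruit = foods["category"].values == "fruit"
        expected = ((scaled.values - base_diet.values)
                    * foods["energy_density_kcal_per_g"].values)[fruit].sum()
        assert de_f == pytest.approx(expected, rel=1e-12)
        assert de_f > 0 and de_v > 0


def _grid_oracle(foods, result_free_energy_target, n_grid=400_001):
    """Exhaustive search over the two free foods' intakes on a fine grid."""
    free = foods[foods["category"] == "other"]
    (b1, e1), (b2, e2) = [(r["baseline_intake_g"], r["energy_density_kcal_per_g"])
                          for _, r in free.iterrows()]
    x1 = np.linspace(0.0, b1 + result_free_energy_target / e1, n_grid)
    x2 = (result_free_energy_target - e1 * x1) / e2
    ok = x2 >= 0
    obj = np.abs(x1 - b1) / b1 + np.abs(x2 - b2) / b2
    return float(obj[ok].min())


class TestDeviationLP:
    def test_ample_pools_leave_free_foods_untouched(self):
        foods = toy_instance(meat_intake=20.0, meat_energy=2.5)  # meat pool 50 kcal
        base = fa.baseline_diet(foods)
        res = fa.build_and_solve_lp(base, foods, fa.PATHWAYS["FV_ALL"])
        assert res.status == "optimal"
        assert res.objective == 0.0
        assert res.diet["o1"] == pytest.approx(200.0)
        assert res.diet["o2"] == pytest.approx(100.0)
        # pools shrank proportionally: fruit +50 kcal from sweet (200 kcal pool)
        assert res.diet["sw"] == pytest.approx(50 * (1 - 50 / 200))
        assert res.diet["mt"] == pytest.approx(20 * (1 - 40 / 50))

    def test_exhausted_meat_pool_matches_grid_oracle(self):
        foods = toy_instance(meat_intake=8.0, meat_energy=2.5)  # pool 20 < 40 kcal
        base = fa.baseline_diet(foods)
        res = fa.build_and_solve_lp(base, foods, fa.PATHWAYS["FV_ALL"])
        assert res.status == "optimal"
        assert res.diet["mt"] == 0.0
        assert any("exhausted" in n for n in res.binding_notes)
        # independently recomputed residual: dE_veg 40 kcal - 20 kcal pool
        residual = 40.0 - 20.0
        free_energy_target = 200 * 1.5 + 100 * 2.0 - residual
        assert res.objective == pytest.approx(
            _grid_oracle(foods, free_energy_target), abs=1e-4)
        summ = fa.summarize_diet(res.diet, foods)
        base_summ = fa.summarize_diet(base, foods)
        assert summ.energy_kcal == pytest.approx(base_summ.energy_kcal, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_instances_match_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sweet_b, meat_b = rng.uniform(2, 30, 2)
        foods = make_foods([
            {"id": "fr", "category": "fruit", "baseline_intake_g": rng.uniform(40, 120),
             "energy_density_kcal_per_g": rng.uniform(0.3, 0.9)},
            {"id": "vg", "category": "vegetable", "baseline_intake_g": rng.uniform(40, 120),
             "energy_density_kcal_per_g": rng.uniform(0.2, 0.8)},
            {"id": "sw", "category": "sweet_snack", "baseline_intake_g": sweet_b,
             "energy_density_kcal_per_g": rng.uniform(3.5, 5.5)},
            {"id": "mt", "category": "red_meat", "baseline_intake_g": meat_b,
             "energy_density_kcal_per_g": rng.uniform(1.5, 3.5)},
            {"id": "o1", "category": "other", "baseline_intake_g": rng.uniform(50, 300),
             "energy_density_kcal_per_g": rng.uniform(0.5, 3.0)},
            {"id": "o2", "category": "other", "baseline_intake_g": rng.uniform(50, 300),
             "energy_density_kcal_per_g": rng.uniform(0.5, 3.0)},
        ])
        base = fa.baseline_diet(foods)
        spec = fa.PATHWAYS["FV_ALL"]
        res = fa.build_and_solve_lp(base, foods, spec)
        assert res.status == "optimal"
        # independent residual arithmetic
        s = fa.solve_scale_factor(base, foods, spec)
        de_f = (s - 1) * base["fr"] * foods.set_index("id").at["fr", "energy_density_kcal_per_g"]
        de_v = (s - 1) * base["vg"] * foods.set_index("id").at["vg", "energy_density_kcal_per_g"]
        fx = foods.set_index("id")
        pool_sw = sweet_b * fx.at["sw", "energy_density_kcal_per_g"]
        pool_mt = meat_b * fx.at["mt", "energy_density_kcal_per_g"]
        residual = max(0.0, de_f - pool_sw) + max(0.0, de_v - pool_mt)
        free_target = (base["o1"] * fx.at["o1", "energy_density_kcal_per_g"]
                       + base["o2"] * fx.at["o2", "energy_density_kcal_per_g"] - residual)
        assert res.objective == pytest.approx(
            _grid_oracle(foods, free_target), abs=1e-4)

    def test_residual_beyond_free_energy_reports_infeasible(self):
        foods = make_foods([
            {"id": "fr", "category": "fruit", "baseline_intake_g": 100,
             "energy_density_kcal_per_g": 0.9},
            {"id": "vg", "category": "vegetable", "baseline_intake_g": 100,
             "energy_density_kcal_per_g": 0.8},
            {"id": "o1", "category": "other", "baseline_intake_g": 10,
             "energy_density_kcal_per_g": 0.5},
        ])
        res = fa.build_and_solve_lp(fa.baseline_diet(foods), foods, fa.PATHWAYS["FV_ALL"])
        assert res.status == "infeasible"
        assert any("energy balance" in n for n in res.binding_notes)


class TestPathwayInvariants:
    def test_energy_conserved_and_target_attained(self, foods, base_diet, pathway_results):
        base_summ = fa.summarize_diet(base_diet, foods)
        for res in pathway_results.values():
            assert res.status == "optimal"
            summ = fa.summarize_diet(res.diet, foods)
            assert abs(summ.energy_kcal - base_summ.energy_kcal) <= 1e-6 * base_summ.energy_kcal
            assert fa.count_five_a_day(res.diet, foods) == pytest.approx(400.0, abs=1e-6)
            assert min(summ.legume_g, 80.0) <= 80.0 + 1e-9

    def test_eligible_foods_scale_proportionally(self, foods, base_diet, pathway_results):
        for pid, res in pathway_results.items():
            elig = fa.eligible_set(foods, fa.PATHWAYS[pid])
            ratios = res.diet[elig] / base_diet[elig]
            assert np.allclose(ratios, res.scale_factor, atol=1e-9)

    def test_monotone_substitution_and_frozen_noneligible(
            self, foods, base_diet, pathway_results):
        cat = foods.set_index("id")["category"]
        for pid, res in pathway_results.items():
            elig = set(fa.eligible_set(foods, fa.PATHWAYS[pid]))
            for fid in foods["id"]:
                if cat[fid] in ("sweet_snack", "red_meat", "processed_meat", "poultry"):
                    assert res.diet[fid] <= base_diet[fid] + 1e-9
                elif cat[fid] in ("fruit", "vegetable", "legume") and fid not in elig:
                    assert res.diet[fid] == pytest.approx(base_diet[fid], rel=1e-12)

    def test_veg_pathways_cut_more_meat(self, foods, base_diet, pathway_results):
        """The stated mechanism for larger GHGE cuts in the VEG pathways."""
        meat = foods["category"].isin(("red_meat", "processed_meat", "poultry")).values
        e = foods["energy_density_kcal_per_g"].values

        def reduction(res):
            d = (base_diet.values - res.diet.values)[meat]
            return d.sum(), (d * e[meat]).sum()

        for fv_id, veg_id in (("FV_ALL", "VEG_ALL"), ("FV_UK", "VEG_UK")):
            g_fv, kcal_fv = reduction(pathway_results[fv_id])
            g_veg, kcal_veg = reduction(pathway_results[veg_id])
            assert g_veg >= g_fv - 1e-9
            assert kcal_veg >= kcal_fv - 1e-9

    def test_run_log_is_json_serializable(self, pathway_results):
        import json
        log = json.dumps(pathway_results["FV_ALL"].run_log())
        assert "scale_factor" in log
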