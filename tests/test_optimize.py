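"""Deviation-minimizing LPs: worked example, invariants, oracle, diagnostics."""

import numpy as np
import pandas as pd
import pytest

import mealopt as mo
from mealopt.breakfast import BreakfastPattern
from mealopt.guidelines import GuidelineSet, NutrientGuideline
from mealopt.optimize import DeviationLP, complementarity_gap


def random_three_food_problem(seed, objective="absolute", infeasible=False):
    """A small LP over 3 random foods: an energy cap (so the feasible set is
    bounded) plus two nutrient floors set either comfortably inside the box
    or far above it."""
    rng = np.random.default_rng(seed)
    comp = mo.generate_composition(10_000 + seed, 3, "random")
    cats = comp.categories
    observed = BreakfastPattern(
        pd.Series(rng.uniform(10, 200, 3), index=cats), population="adults"
    )
    anchor = pd.Series(rng.uniform(20, 300, 3), index=cats)
    nut = comp.nutrients_of(anchor)
    floor_scale = 50.0 if infeasible else 0.8
    gls = [
        NutrientGuideline(
            "energy_kcal", "absolute", "max", (float(nut["energy_kcal"] * 1.3),)
        )
    ]
    picks = rng.choice(["calcium_mg", "protein_g", "iron_mg", "fiber_g"], 2, replace=False)
    gls += [
        NutrientGuideline(str(n), "absolute", "min", (float(nut[n] * floor_scale),))
        for n in picks
    ]
    system = mo.compile_constraints(GuidelineSet(gls), comp, "adults")
    return DeviationLP(observed, system, objective)


class TestCalciumWorkedExample:
    def test_relative_moves_milk(self, calcium_problem):
        """The relative objective raises milk to 275 g (+10 %, distance 0.1)
        and leaves cheese at 30 g."""
        sol = mo.solve_relative(calcium_problem)
        assert sol.status == "optimal"
        assert sol.optimized.quantities["milk"] == pytest.approx(275.0, abs=1e-6)
        assert sol.optimized.quantities["cheese"] == pytest.approx(30.0, abs=1e-6)
        assert sol.distance == pytest.approx(0.1, abs=1e-8)

    def test_absolute_moves_cheese(self, calcium_problem):
        """The absolute objective raises cheese by 5 g (5 g beats 25 g of
        milk) and leaves milk at 250 g."""
        sol = mo.solve_absolute(calcium_problem)
        assert sol.status == "optimal"
        assert sol.optimized.quantities["cheese"] == pytest.approx(35.0, abs=1e-6)
        assert sol.optimized.quantities["milk"] == pytest.approx(250.0, abs=1e-6)
        assert sol.distance == pytest.approx(5.0, abs=1e-6)

    def test_objectives_pick_different_foods(self, calcium_problem):
        rel = mo.solve_relative(calcium_problem)
        ab = mo.solve_absolute(calcium_problem)
        moved_rel = rel.per_category_change["delta_g"].abs().idxmax()
        moved_ab = ab.per_category_change["delta_g"].abs().idxmax()
        assert {moved_rel, moved_ab} == {"milk", "cheese"}

    def test_calcium_constraint_binds(self, calcium, calcium_problem):
        comp, _, _ = calcium
        for solve in (mo.solve_relative, mo.solve_absolute):
            sol = solve(calcium_problem)
            assert sol.binding == ["calcium_mg:min"]
            assert sol.nutrients(comp)["calcium_mg"] == pytest.approx(510.0, abs=1e-6)

    def test_oracle_agrees_on_the_example(self, calcium_problem):
        rel = DeviationLP(
            calcium_problem.observed, calcium_problem.constraints, "relative"
        )
        orc = mo.brute_force_oracle(rel, grid_step=0.5)
        assert orc.status == "optimal"
        assert orc.optimized.quantities["milk"] == pytest.approx(275.0, abs=0.5)


class TestFeasibleStart:
    def test_already_compliant_pattern_unchanged(self, calcium):
        comp, _, gl = calcium
        rich = BreakfastPattern(
            pd.Series({"milk": 300.0, "cheese": 40.0}), population="adults"
        )
        base = DeviationLP.from_guidelines(rich, comp, gl, "adults")
        for solve in (mo.solve_relative, mo.solve_absolute):
            sol = solve(base)
            assert sol.distance == pytest.approx(0.0, abs=1e-9)
            np.testing.assert_allclose(
                sol.optimized.quantities.values, rich.quantities.values, atol=1e-9
            )


class TestRelativeObjectiveBehavior:
    def test_zero_observed_categories_stay_zero(self, calcium):
        """Foods not eaten at all cannot enter under the relative objective."""
        comp, _, gl = calcium
        observed = BreakfastPattern(
            pd.Series({"milk": 250.0, "cheese": 0.0}), population="adults"
        )
        base = DeviationLP.from_guidelines(observed, comp, gl, "adults")
        sol = mo.solve_relative(base)
        assert sol.status == "optimal"
        assert sol.optimized.quantities["cheese"] == 0.0
        assert sol.optimized.quantities["milk"] == pytest.approx(425.0, abs=1e-6)

    def test_all_zero_observed_with_binding_minimum_infeasible(self, calcium):
        comp, _, gl = calcium
        observed = BreakfastPattern(
            pd.Series({"milk": 0.0, "cheese": 0.0}), population="adults"
        )
        base = DeviationLP.from_guidelines(observed, comp, gl, "adults")
        sol = mo.solve_relative(base)
        assert sol.status == "infeasible"
        assert "calcium_mg:min" in sol.diagnostics.index

    def test_unit_invariance(self):
        """Rescaling a food's gram unit (quantity down, densities up) leaves
        the relative distance unchanged."""
        density = pd.DataFrame({"calcium_mg": {"a": 100.0, "b": 400.0}})
        gl = GuidelineSet([NutrientGuideline("calcium_mg", "absolute", "min", (500.0,))])

        def solve_with(scale):
            d = density.copy()
            d.loc["a", "calcium_mg"] *= scale
            comp = mo.CompositionMatrix(d)
            obs = BreakfastPattern(
                pd.Series({"a": 200.0 / scale, "b": 50.0}), population="adults"
            )
            return mo.solve_relative(DeviationLP.from_guidelines(obs, comp, gl, "adults"))

        assert solve_with(1.0).distance == pytest.approx(solve_with(4.0).distance, abs=1e-8)


class TestInfeasibility:
    def test_infeasible_reports_violated_rows_without_raising(self, seed=5):
        problem = random_three_food_problem(seed, infeasible=True)
        sol = problem.fit()
        assert sol.status == "infeasible"
        assert sol.optimized is None and sol.distance is None
        assert len(sol.diagnostics) >= 1
        assert (sol.diagnostics > 0).all()
        assert "violated" in sol.summary() or "infeasible" in sol.summary()

    def test_oracle_agrees_on_infeasibility(self):
        problem = random_three_food_problem(6, infeasible=True)
        orc = mo.brute_force_oracle(problem)
        assert orc.status == "infeasible"


class TestOracleEquivalence:
    @pytest.mark.parametrize("objective", ["absolute", "relative"])
    def test_lp_matches_grid_search(self, objective):
        """On small random problems the LP objective agrees with exhaustive
        grid search within the grid tolerance, and both agree on
        feasibility."""
        for seed in range(15):
            problem = random_three_food_problem(seed, objective=objective)
            lp = problem.fit()
            orc = mo.brute_force_oracle(problem)
            assert lp.status == orc.status
            if lp.status != "optimal":
                continue
            weights, _ = problem._weights_and_fixed()
            a_ub, _ = problem.constraints.as_upper_bound()
            ub = max(problem.observed.quantities.max() * 10 + 1000, 1.0)
            step = ub / 60.0  # matches the oracle's automatic choice ceiling
            tol = 2.0 * step * float(np.sum(weights)) + 1e-6
            assert abs(lp.distance - orc.distance) <= tol

    def test_strictly_feasible_oracle_point_never_beats_lp(self):
        """Any strictly feasible grid point is LP-feasible, so the oracle
        cannot undercut the LP optimum."""
        for seed in range(10):
            problem = random_three_food_problem(seed)
            lp = problem.fit()
            orc = mo.brute_force_oracle(problem)
            if lp.status != "optimal" or orc.status != "optimal":
                continue
            if problem.constraints.satisfied(orc.optimized.quantities, tol=1e-9):
                assert orc.distance >= lp.distance - 1e-6

    def test_too_many_free_categories_rejected(self, comp31, t1_children):
        gset = mo.default_guidelines("children")
        system = mo.compile_constraints(gset, comp31, "children")
        problem = DeviationLP(t1_children, system, "absolute")
        with pytest.raises(ValueError, match="free categories"):
            mo.brute_force_oracle(problem, grid_step=10.0)


class TestSolutionInvariants:
    def test_complementarity(self):
        for seed in range(8):
            sol = random_three_food_problem(seed).fit()
            if sol.status == "optimal":
                assert complementarity_gap(sol) <= 1e-8

    def test_distance_recomputable_from_patterns(self):
        for seed in range(8):
            problem = random_three_food_problem(seed, objective="relative")
            sol = problem.fit()
            if sol.status != "optimal":
                continue
            obs = problem.observed.quantities
            x = sol.optimized.quantities
            direct = float((np.abs(x - obs) / obs.where(obs > 0, np.inf)).sum())
            assert sol.distance == pytest.approx(direct, abs=1e-6)

    def test_constraints_satisfied_at_optimum(self):
        for seed in range(8):
            problem = random_three_food_problem(seed)
            sol = problem.fit()
            if sol.status == "optimal":
                assert problem.constraints.satisfied(sol.optimized.quantities, tol=1e-6)
                assert (sol.optimized.quantities >= 0).all()

    def test_relaxing_a_bound_never_increases_distance(self, calcium):
        comp, obs, _ = calcium
        distances = []
        for floor in (510.0, 500.0, 490.0):
            gl = GuidelineSet(
                [NutrientGuideline("calcium_mg", "absolute", "min", (floor,))]
            )
            base = DeviationLP.from_guidelines(obs, comp, gl, "adults")
            distances.append(mo.solve_absolute(base).distance)
        assert distances == sorted(distances, reverse=True)


class TestOptimizeT1:
    def test_both_solutions_meet_every_guideline(self, comp31, t1_children):
        gset = mo.default_guidelines("children")
        rel, ab = mo.optimize_t1("children", comp31, t1_children)
        for sol in (rel, ab):
            assert sol.status == "optimal"
            nut = sol.nutrients(comp31)
            for g in gset.guidelines:
                assert g.satisfied_by(nut, tol=1e-6), g

    def test_processed_meat_not_increased(self, comp31, t1_children, t1_adults):
        """With saturated-fat and sodium constraints active, neither
        objective has reason to add processed meat."""
        for pop, t1 in (("children", t1_children), ("adults", t1_adults)):
            rel, ab = mo.optimize_t1(pop, comp31, t1)
            for sol in (rel, ab):
                assert (
                    sol.optimized.quantities["processed_meat"]
                    <= t1.quantities["processed_meat"] + 1e-9
                )

    def test_impossibly_strict_guidelines_report_infeasible(self, comp31, t1_children):
        strict = GuidelineSet(
            [
                NutrientGuideline("energy_kcal", "absolute", "max", (100.0,)),
                NutrientGuideline("calcium_mg", "absolute", "min", (5000.0,)),
            ],
            label="impossible",
        )
        rel, ab = mo.optimize_t1("children", comp31, t1_children, strict)
        for sol in (rel, ab):
            assert sol.status == "infeasible"
            assert len(sol.diagnostics) >= 1
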