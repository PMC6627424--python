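"""NRF9.3 scoring: subscores, capping, energy adjustment, tertiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mealopt as mo
from mealopt.nrf import DEFAULT_DV, DEFAULT_MRV, NRFParameters, ScoredPerson


def intake_at(dv_factor=1.0, mrv_factor=1.0, energy=2000.0):
    amounts = {"energy_kcal": energy}
    for nut, dv in DEFAULT_DV.items():
        amounts[nut] = dv * dv_factor
    for nut, mrv in DEFAULT_MRV.items():
        amounts[nut] = mrv * mrv_factor
    return mo.nutrient_vector(amounts)


class TestNR:
    @pytest.mark.parametrize(
        "dv_factor,energy,expected",
        [
            (1.0, 2000.0, 9.0),   # every qualifying nutrient exactly at its DV
            (2.0, 2000.0, 9.0),   # truncation at 100 %DV
            (0.5, 1000.0, 9.0),   # the 2000-kcal adjustment doubles each ratio
            (0.5, 2000.0, 4.5),
            (0.0, 2000.0, 0.0),
        ],
    )
    def test_capped_dv_sum(self, dv_factor, energy, expected):
        assert mo.compute_nr(intake_at(dv_factor, 0.0, energy)) == pytest.approx(expected)

    def test_zero_energy_rejected(self):
        with pytest.raises(ValueError, match="energy"):
            mo.compute_nr(intake_at(energy=0.0))

    def test_missing_nutrient_named(self):
        intake = intake_at().drop("calcium_mg")
        with pytest.raises(KeyError, match="calcium_mg"):
            mo.compute_nr(intake)


class TestLIM:
    @pytest.mark.parametrize(
        "mrv_factor,expected",
        [(1.0, 0.0), (0.0, 0.0), (2.0, 3.0)],
    )
    def test_excess_only(self, mrv_factor, expected):
        assert mo.compute_lim(intake_at(0.0, mrv_factor)) == pytest.approx(expected)

    def test_single_nutrient_excess(self):
        """Sodium at 4600 mg (double its MRV) contributes exactly 1."""
        intake = intake_at(0.0, 1.0)
        intake["sodium_mg"] = 4600.0
        assert mo.compute_lim(intake) == pytest.approx(1.0)


class TestNRF93:
    @pytest.mark.parametrize(
        "dv_factor,mrv_factor,expected",
        [(1.0, 1.0, 900.0), (0.0, 0.0, 0.0)],
    )
    def test_score_scale(self, dv_factor, mrv_factor, expected):
        assert mo.compute_nrf93(intake_at(dv_factor, mrv_factor)) == pytest.approx(expected)

    def test_limiting_excess_subtracts(self):
        intake = intake_at(1.0, 1.0)
        intake["sodium_mg"] = 2 * DEFAULT_MRV["sodium_mg"]
        assert mo.compute_nrf93(intake) == pytest.approx(800.0)

    @given(
        dv=st.floats(0.0, 5.0),
        mrv=st.floats(0.0, 5.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_energy_adjustment_invariance(self, dv, mrv, scale):
        """Scaling every nutrient and energy by a common factor leaves the
        score unchanged: NRF9.3 is a per-2000-kcal density measure."""
        base = intake_at(dv, mrv)
        scaled = base * scale
        assert mo.compute_nrf93(scaled) == pytest.approx(
            mo.compute_nrf93(base), rel=1e-9, abs=1e-9
        )

    @given(
        dv=st.floats(0.0, 3.0),
        mrv=st.floats(0.0, 3.0),
        nutrient=st.sampled_from(sorted(DEFAULT_DV) + sorted(DEFAULT_MRV)),
        bump=st.floats(0.1, 500.0),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_monotonicity(self, dv, mrv, nutrient, bump):
        """More of a qualifying nutrient never lowers the score; more of a
        limiting nutrient never raises it (energy held fixed)."""
        base = intake_at(dv, mrv)
        bumped = base.copy()
        bumped[nutrient] += bump
        delta = mo.compute_nrf93(bumped) - mo.compute_nrf93(base)
        if nutrient in DEFAULT_DV:
            assert delta >= -1e-9
        else:
            assert delta <= 1e-9

    @given(dv=st.floats(0.0, 10.0), mrv=st.floats(0.0, 10.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_upper_bound_900(self, dv, mrv):
        score = mo.compute_nrf93(intake_at(dv, mrv))
        assert score <= 900.0 + 1e-9
        if dv >= 1.0 and mrv <= 1.0:
            assert score == pytest.approx(900.0)


class TestParameters:
    def test_default_counts(self):
        params = NRFParameters.default()
        assert len(params.qualifying) == 9
        assert len(params.limiting) == 3
        assert "vitamin_d_ug" in params.qualifying  # vitamin D, not E

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "nrf.yaml"
        payload = {
            "qualifying": dict(DEFAULT_DV),
            "limiting": dict(DEFAULT_MRV),
            "energy_basis_kcal": 2000,
        }
        path.write_text(yaml.safe_dump(payload))
        params = NRFParameters.from_yaml(path)
        assert params.qualifying == DEFAULT_DV
        assert params.energy_basis_kcal == 2000

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            NRFParameters(qualifying={"protein_g": 0.0}, limiting=dict(DEFAULT_MRV))


def make_scored(scores, age_group="children", prefix="p"):
    return [
        ScoredPerson(f"{prefix}{i:02d}", age_group, 0.0, 0.0, s)
        for i, s in enumerate(scores)
    ]


class TestTertiles:
    def test_divisible_group(self):
        people = mo.assign_tertiles(make_scored(range(9)))
        counts = {t: sum(p.tertile == t for p in people) for t in ("T1", "T2", "T3")}
        assert counts == {"T1": 3, "T2": 3, "T3": 3}

    def test_remainder_goes_to_lower_tertiles(self):
        """With scores 1..10 the extra member lands in T1: sizes {4, 3, 3},
        so persons with the four lowest scores form T1."""
        people = mo.assign_tertiles(make_scored(range(1, 11)))
        by_score = {p.nrf93: p.tertile for p in people}
        assert [by_score[s] for s in range(1, 11)] == (
            ["T1"] * 4 + ["T2"] * 3 + ["T3"] * 3
        )

    def test_age_groups_stratified_independently(self):
        children = make_scored([10, 20, 30], "children", "c")
        adults = make_scored([1, 2, 3, 1000, 2000, 3000], "adults", "a")
        people = mo.assign_tertiles(children + adults)
        child_tertiles = [p.tertile for p in people if p.age_group == "children"]
        assert child_tertiles == ["T1", "T2", "T3"]

    def test_ties_broken_by_person_id(self):
        a = mo.assign_tertiles(make_scored([5, 5, 5, 5, 5, 5]))
        b = mo.assign_tertiles(make_scored([5, 5, 5, 5, 5, 5]))
        assert [p.tertile for p in a] == [p.tertile for p in b]

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="members"):
            mo.assign_tertiles(make_scored([1, 2]))
        with pytest.raises(ValueError):
            mo.assign_tertiles([])

    def test_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(0)
        for n in (3, 4, 5, 7, 11, 100):
            people = mo.assign_tertiles(make_scored(rng.uniform(0, 900, n)))
            counts = [sum(p.tertile == t for p in people) for t in ("T1", "T2", "T3")]
            assert max(counts) - min(counts) <= 1
            assert sum(counts) == n
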