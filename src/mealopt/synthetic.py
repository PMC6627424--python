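"""Synthetic dietary-survey data and packaged in-study fixtures.

Everything the pipeline needs can be generated here without external
downloads: food-composition matrices, intake populations with labelled
meals and realistic breakfast behaviour (including skippers), the
packaged bottom-tertile mean breakfast patterns, and the small two-food
calcium example that contrasts the two LP objectives.

The ``paper_like`` composition profile anchors a set of breakfast-typical
categories (milk, cheese, eggs, processed meat, sweet bakery, mixed
dishes, fruit, juice, cereals, nuts, coffee, yogurt) at realistic
per-100 g nutrient profiles — in particular milk at 48 kcal and 1 g SFA,
cheese at 290 kcal and 12 g SFA, processed meat at 290 kcal and 7 g SFA,
sweet bakery at 400 kcal and 7 g SFA, eggs at 180 kcal and 4.5 g SFA and
mixed dishes at 215 kcal and 3.7 g SFA — and draws the remaining
categories from log-uniform ranges bracketing those profiles, so the
resulting LPs are well-scaled and feasible under the packaged breakfast
guidelines.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .breakfast import BreakfastPattern
from .catalog import catalog_ids, default_catalog
from .composition import NUTRIENTS, CompositionMatrix, nutrient_vector
from .guidelines import GuidelineSet, NutrientGuideline
from .nrf import DEFAULT_DV, DEFAULT_MRV
from .records import IntakeRecord, Meal

# --------------------------------------------------------------------------
# composition generation
# --------------------------------------------------------------------------

# Realistic per-100 g profiles for breakfast-typical categories.  The milk /
# cheese / processed-meat / sweet-bakery / eggs / mixed-dishes energy and SFA
# values are the anchors the rest of the fixture is built around.
_ANCHORED: dict[str, dict[str, float]] = {
    "milk": dict(energy_kcal=48, protein_g=3.4, carbohydrate_g=5.0, fat_g=1.9,
                 sfa_g=1.0, mufa_g=0.5, pufa_g=0.1, added_sugar_g=0.0, fiber_g=0.0,
                 sodium_mg=40, calcium_mg=120, iron_mg=0.03, potassium_mg=150,
                 magnesium_mg=11, zinc_mg=0.4, vitamin_a_ug=55, vitamin_c_mg=0.1,
                 vitamin_d_ug=1.1, thiamin_mg=0.04, riboflavin_mg=0.17,
                 niacin_mg=0.1, vitamin_b6_mg=0.04, vitamin_b12_ug=0.5, folate_ug=5),
    "cheese": dict(energy_kcal=290, protein_g=20, carbohydrate_g=3.0, fat_g=22,
                   sfa_g=12.0, mufa_g=6.0, pufa_g=0.8, added_sugar_g=0.0, fiber_g=0.0,
                   sodium_mg=650, calcium_mg=600, iron_mg=0.4, potassium_mg=100,
                   magnesium_mg=25, zinc_mg=3.0, vitamin_a_ug=250, vitamin_c_mg=0.0,
                   vitamin_d_ug=0.4, thiamin_mg=0.03, riboflavin_mg=0.35,
                   niacin_mg=0.1, vitamin_b6_mg=0.07, vitamin_b12_ug=1.0, folate_ug=15),
    "processed_meat": dict(energy_kcal=290, protein_g=15, carbohydrate_g=2.0, fat_g=25,
                           sfa_g=7.0, mufa_g=11, pufa_g=3.0, added_sugar_g=0.5, fiber_g=0.0,
                           sodium_mg=1000, calcium_mg=10, iron_mg=1.0, potassium_mg=250,
                           magnesium_mg=15, zinc_mg=2.0, vitamin_a_ug=10, vitamin_c_mg=0.0,
                           vitamin_d_ug=0.6, thiamin_mg=0.3, riboflavin_mg=0.15,
                           niacin_mg=4.0, vitamin_b6_mg=0.25, vitamin_b12_ug=1.0, folate_ug=3),
    "sweet_bakery": dict(energy_kcal=400, protein_g=5.0, carbohydrate_g=55, fat_g=18,
                         sfa_g=7.0, mufa_g=7.0, pufa_g=3.0, added_sugar_g=25, fiber_g=1.5,
                         sodium_mg=350, calcium_mg=50, iron_mg=2.0, potassium_mg=120,
                         magnesium_mg=15, zinc_mg=0.6, vitamin_a_ug=60, vitamin_c_mg=0.2,
                         vitamin_d_ug=0.3, thiamin_mg=0.25, riboflavin_mg=0.25,
                         niacin_mg=2.0, vitamin_b6_mg=0.04, vitamin_b12_ug=0.2, folate_ug=60),
    "eggs": dict(energy_kcal=180, protein_g=12.5, carbohydrate_g=1.0, fat_g=13.5,
                 sfa_g=4.5, mufa_g=5.0, pufa_g=2.0, added_sugar_g=0.0, fiber_g=0.0,
                 sodium_mg=200, calcium_mg=55, iron_mg=1.7, potassium_mg=135,
                 magnesium_mg=12, zinc_mg=1.2, vitamin_a_ug=160, vitamin_c_mg=0.0,
                 vitamin_d_ug=2.0, thiamin_mg=0.05, riboflavin_mg=0.45,
                 niacin_mg=0.08, vitamin_b6_mg=0.15, vitamin_b12_ug=1.0, folate_ug=45),
    "mixed_dishes": dict(energy_kcal=215, protein_g=9.0, carbohydrate_g=20, fat_g=11,
                         sfa_g=3.7, mufa_g=4.5, pufa_g=2.0, added_sugar_g=1.0, fiber_g=1.5,
                         sodium_mg=500, calcium_mg=100, iron_mg=1.5, potassium_mg=200,
                         magnesium_mg=20, zinc_mg=1.2, vitamin_a_ug=60, vitamin_c_mg=2.0,
                         vitamin_d_ug=0.3, thiamin_mg=0.2, riboflavin_mg=0.25,
                         niacin_mg=2.5, vitamin_b6_mg=0.12, vitamin_b12_ug=0.5, folate_ug=50),
    "rte_cereal_low_sugar": dict(energy_kcal=380, protein_g=12, carbohydrate_g=74, fat_g=6,
                                 sfa_g=1.2, mufa_g=2.0, pufa_g=2.0, added_sugar_g=4.0, fiber_g=10,
                                 sodium_mg=500, calcium_mg=350, iron_mg=30, potassium_mg=600,
                                 magnesium_mg=130, zinc_mg=12, vitamin_a_ug=500, vitamin_c_mg=20,
                                 vitamin_d_ug=7.0, thiamin_mg=1.2, riboflavin_mg=1.4,
                                 niacin_mg=16, vitamin_b6_mg=1.7, vitamin_b12_ug=6.0, folate_ug=600),
    "rte_cereal_high_sugar": dict(energy_kcal=390, protein_g=6.0, carbohydrate_g=85, fat_g=3,
                                  sfa_g=0.8, mufa_g=1.0, pufa_g=1.0, added_sugar_g=35, fiber_g=4,
                                  sodium_mg=450, calcium_mg=120, iron_mg=18, potassium_mg=200,
                                  magnesium_mg=40, zinc_mg=6.0, vitamin_a_ug=450, vitamin_c_mg=18,
                                  vitamin_d_ug=4.0, thiamin_mg=1.0, riboflavin_mg=1.2,
                                  niacin_mg=14, vitamin_b6_mg=1.4, vitamin_b12_ug=4.5, folate_ug=450),
    "fruit": dict(energy_kcal=60, protein_g=0.7, carbohydrate_g=14, fat_g=0.25,
                  sfa_g=0.05, mufa_g=0.05, pufa_g=0.08, added_sugar_g=0.0, fiber_g=2.4,
                  sodium_mg=1, calcium_mg=12, iron_mg=0.25, potassium_mg=180,
                  magnesium_mg=12, zinc_mg=0.1, vitamin_a_ug=25, vitamin_c_mg=30,
                  vitamin_d_ug=0.0, thiamin_mg=0.03, riboflavin_mg=0.04,
                  niacin_mg=0.4, vitamin_b6_mg=0.08, vitamin_b12_ug=0.0, folate_ug=12),
    "juice_100": dict(energy_kcal=46, protein_g=0.6, carbohydrate_g=10.5, fat_g=0.15,
                      sfa_g=0.03, mufa_g=0.03, pufa_g=0.05, added_sugar_g=0.0, fiber_g=0.3,
                      sodium_mg=2, calcium_mg=12, iron_mg=0.2, potassium_mg=190,
                      magnesium_mg=10, zinc_mg=0.05, vitamin_a_ug=8, vitamin_c_mg=38,
                      vitamin_d_ug=0.0, thiamin_mg=0.06, riboflavin_mg=0.03,
                      niacin_mg=0.3, vitamin_b6_mg=0.06, vitamin_b12_ug=0.0, folate_ug=20),
    "nuts_beans_soy": dict(energy_kcal=520, protein_g=19, carbohydrate_g=22, fat_g=42,
                           sfa_g=6.0, mufa_g=22, pufa_g=11, added_sugar_g=1.0, fiber_g=8,
                           sodium_mg=150, calcium_mg=100, iron_mg=3.5, potassium_mg=650,
                           magnesium_mg=230, zinc_mg=3.0, vitamin_a_ug=2, vitamin_c_mg=0.5,
                           vitamin_d_ug=0.0, thiamin_mg=0.3, riboflavin_mg=0.3,
                           niacin_mg=4.0, vitamin_b6_mg=0.25, vitamin_b12_ug=0.0, folate_ug=90),
    "coffee_tea": dict(energy_kcal=2, protein_g=0.2, carbohydrate_g=0.3, fat_g=0.02,
                       sfa_g=0.01, mufa_g=0.0, pufa_g=0.0, added_sugar_g=0.0, fiber_g=0.0,
                       sodium_mg=3, calcium_mg=3, iron_mg=0.02, potassium_mg=50,
                       magnesium_mg=4, zinc_mg=0.02, vitamin_a_ug=0.0, vitamin_c_mg=0.0,
                       vitamin_d_ug=0.0, thiamin_mg=0.01, riboflavin_mg=0.08,
                       niacin_mg=0.5, vitamin_b6_mg=0.001, vitamin_b12_ug=0.0, folate_ug=3),
    "yogurt": dict(energy_kcal=85, protein_g=5.0, carbohydrate_g=12, fat_g=2.2,
                   sfa_g=1.4, mufa_g=0.6, pufa_g=0.1, added_sugar_g=7.0, fiber_g=0.0,
                   sodium_mg=60, calcium_mg=150, iron_mg=0.05, potassium_mg=200,
                   magnesium_mg=14, zinc_mg=0.7, vitamin_a_ug=30, vitamin_c_mg=0.6,
                   vitamin_d_ug=0.8, thiamin_mg=0.04, riboflavin_mg=0.2,
                   niacin_mg=0.15, vitamin_b6_mg=0.05, vitamin_b12_ug=0.45, folate_ug=9),
}

# log-uniform [low, high] sampling ranges per 100 g for non-anchored
# categories; macro-derived energy keeps percent-energy constraints sane
_MICRO_RANGES: dict[str, tuple[float, float]] = {
    "fiber_g": (0.1, 8.0),
    "sodium_mg": (5.0, 800.0),
    "calcium_mg": (5.0, 300.0),
    "iron_mg": (0.05, 5.0),
    "potassium_mg": (30.0, 500.0),
    "magnesium_mg": (2.0, 100.0),
    "zinc_mg": (0.05, 4.0),
    "vitamin_a_ug": (1.0, 250.0),
    "vitamin_c_mg": (0.2, 40.0),
    "vitamin_d_ug": (0.02, 2.0),
    "thiamin_mg": (0.01, 0.6),
    "riboflavin_mg": (0.01, 0.6),
    "niacin_mg": (0.05, 6.0),
    "vitamin_b6_mg": (0.01, 0.6),
    "vitamin_b12_ug": (0.01, 2.0),
    "folate_ug": (2.0, 150.0),
}


def _loguniform(rng: np.random.Generator, low: float, high: float, size=None):
    return np.exp(rng.uniform(np.log(low), np.log(high), size=size))


def _random_profile(rng: np.random.Generator, beverage: bool) -> dict[str, float]:
    scale = 0.08 if beverage else 1.0
    protein = _loguniform(rng, 0.5, 20.0) * scale
    carb = _loguniform(rng, 2.0, 70.0) * scale
    fat = _loguniform(rng, 0.1, 25.0) * scale
    profile = {
        "protein_g": protein,
        "carbohydrate_g": carb,
        "fat_g": fat,
        "sfa_g": fat * rng.uniform(0.2, 0.55),
        "mufa_g": fat * rng.uniform(0.2, 0.45),
        "pufa_g": fat * rng.uniform(0.05, 0.3),
        "added_sugar_g": carb * rng.uniform(0.0, 0.5),
        "energy_kcal": 4.0 * (protein + carb) + 9.0 * fat,
    }
    for nut, (lo, hi) in _MICRO_RANGES.items():
        profile[nut] = _loguniform(rng, lo, hi) * (scale if beverage else 1.0)
    return profile


def generate_composition(
    seed: int, n_categories: int, profile: str = "paper_like"
) -> CompositionMatrix:
    """Generate a deterministic food-composition matrix.

    ``profile="paper_like"`` requires ``n_categories=31`` and returns the
    full WWEIA catalog with the anchored breakfast-food profiles described
    in the module docstring and randomized but plausible values elsewhere.
    ``profile="random"`` returns ``n_categories`` generic categories
    (``cat00`` ...) with fully randomized profiles, for small stress-test
    problems.
    """
    if n_categories < 2:
        raise ValueError("need at least 2 categories")
    if profile not in ("paper_like", "random"):
        raise ValueError(f"unknown composition profile {profile!r}")
    rng = np.random.default_rng(seed)

    if profile == "paper_like":
        if n_categories != 31:
            raise ValueError("paper_like profile is defined over the 31-category catalog")
        rows = {}
        for cat in default_catalog():
            if cat.id in _ANCHORED:
                rows[cat.id] = dict(_ANCHORED[cat.id])
                # keep the stream position identical whether or not a
                # category is anchored, so anchors don't shift the rest
                _random_profile(rng, beverage=False)
            else:
                rows[cat.id] = _random_profile(rng, beverage=cat.group == "Beverages")
        frame = pd.DataFrame.from_dict(rows, orient="index").loc[catalog_ids(), list(NUTRIENTS)]
        return CompositionMatrix(frame)

    ids = [f"cat{i:02d}" for i in range(n_categories)]
    rows = {cid: _random_profile(rng, beverage=False) for cid in ids}
    frame = pd.DataFrame.from_dict(rows, orient="index").loc[ids, list(NUTRIENTS)]
    return CompositionMatrix(frame)


# --------------------------------------------------------------------------
# population generation
# --------------------------------------------------------------------------

# breakfast inclusion probability and typical serving (g) per category
_BREAKFAST_HABITS: dict[str, tuple[float, float]] = {
    "coffee_tea": (0.35, 240), "diet_beverages": (0.05, 250),
    "sweetened_beverages": (0.2, 250), "fats_oils": (0.25, 8),
    "fruit": (0.25, 110), "juice_100": (0.2, 180), "breads": (0.3, 50),
    "cooked_grains": (0.15, 120), "grains": (0.05, 40), "quick_breads": (0.15, 60),
    "rte_cereal_high_sugar": (0.2, 35), "rte_cereal_low_sugar": (0.2, 35),
    "cheese": (0.12, 25), "flavored_milk": (0.08, 200), "milk": (0.55, 200),
    "milk_dessert_drinks": (0.03, 120), "yogurt": (0.12, 120),
    "mixed_dishes": (0.18, 150), "eggs": (0.3, 90), "nuts_beans_soy": (0.12, 25),
    "processed_meat": (0.18, 40), "seafood_meat": (0.05, 60), "candy": (0.04, 20),
    "crackers": (0.04, 20), "other_desserts": (0.04, 60), "savory_snacks": (0.05, 25),
    "snack_meal_bars": (0.07, 40), "sweet_bakery": (0.25, 70), "sugars": (0.3, 10),
    "vegetables_nonpotato": (0.08, 60), "white_potatoes": (0.1, 80),
}
_FALLBACK_HABIT = (0.3, 80.0)


def _sample_items(rng, categories, quality: float) -> list[tuple[str, float]]:
    items = []
    for cid in categories:
        prob, serving = _BREAKFAST_HABITS.get(cid, _FALLBACK_HABIT)
        if cid == "fruit":  # higher-quality diets eat more morning fruit
            prob = 0.15 + 0.55 * quality
        if rng.uniform() < prob:
            grams = serving * float(np.exp(rng.normal(0.0, 0.4)))
            items.append((cid, round(grams, 1)))
    if not items:  # everyone who eats, eats something
        cid = categories[rng.integers(len(categories))]
        items.append((cid, _BREAKFAST_HABITS.get(cid, _FALLBACK_HABIT)[1]))
    return items


def _scale_items(items, factor):
    return [(c, g * factor) for c, g in items]


def generate_population(
    seed: int,
    n: int,
    breakfast_skipper_rate: float,
    composition: CompositionMatrix,
) -> list[IntakeRecord]:
    """Generate ``n`` intake records with labelled meals and day totals.

    Approximately ``breakfast_skipper_rate`` of the records either carry no
    breakfast-labelled meal or a morning meal below 50 kcal.  Children
    (6-17) and adults are both represented.  A latent diet-quality draw per
    person links whole-day nutrient adequacy to morning fruit intake, so
    downstream tertiles recover a fruit gradient.  Day totals equal the
    itemized meals times the composition matrix plus a nonnegative
    non-breakfast aggregate remainder.
    """
    if not 0.0 <= breakfast_skipper_rate <= 1.0:
        raise ValueError("breakfast_skipper_rate must lie in [0, 1]")
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    cats = composition.categories
    records: list[IntakeRecord] = []

    for i in range(n):
        person_id = f"P{i:05d}"
        is_child = rng.uniform() < 0.4
        age = int(rng.integers(6, 18)) if is_child else int(rng.integers(18, 86))
        quality = float(rng.uniform())
        skipper = rng.uniform() < breakfast_skipper_rate

        meals: list[Meal] = []
        bf_items = _sample_items(rng, cats, quality)
        bf_energy = float(composition.nutrients_of(dict(bf_items))["energy_kcal"])

        if skipper and rng.uniform() < 0.5:
            pass  # no morning meal at all
        else:
            if skipper:
                target = float(rng.uniform(5.0, 45.0))  # sub-threshold episode
                bf_items = _scale_items(bf_items, target / max(bf_energy, 1e-9))
            elif bf_energy < 60.0:
                bf_items = _scale_items(bf_items, 80.0 / max(bf_energy, 1e-9))
            label = rng.choice(["Breakfast", "breakfast", "desayuno", "Brunch"],
                               p=[0.55, 0.25, 0.08, 0.12])
            if not skipper and rng.uniform() < 0.06:
                # split the morning into separate breakfast + brunch episodes
                half = len(bf_items) // 2 or 1
                meals.append(Meal("Breakfast", bf_items[:half]))
                meals.append(Meal("Brunch", bf_items[half:]))
            else:
                meals.append(Meal(str(label), bf_items))

        lunch_items = [
            (cid, round(float(_BREAKFAST_HABITS.get(cid, _FALLBACK_HABIT)[1]
                              * np.exp(rng.normal(0, 0.4))), 1))
            for cid in rng.choice(cats, size=rng.integers(2, 5), replace=False)
        ]
        meals.append(Meal("Lunch", lunch_items))

        itemized = composition.nutrients_of(
            {**{}, **_sum_items([it for m in meals for it in m.items])}
        )
        remainder = _remainder_vector(rng, quality)
        day = itemized.add(remainder, fill_value=0.0)
        records.append(IntakeRecord(person_id, age, meals, day))
    return records


def _sum_items(items: list[tuple[str, float]]) -> dict[str, float]:
    out: dict[str, float] = {}
    for cid, grams in items:
        out[cid] = out.get(cid, 0.0) + grams
    return out


def _remainder_vector(rng: np.random.Generator, quality: float):
    """Aggregate non-breakfast rest-of-day nutrients, tilted by diet quality."""
    amounts = {"energy_kcal": float(rng.uniform(800.0, 1600.0))}
    for nut, dv in DEFAULT_DV.items():
        amounts[nut] = dv * (0.25 + 0.75 * quality) * float(rng.uniform(0.5, 1.0))
    for nut, mrv in DEFAULT_MRV.items():
        amounts[nut] = mrv * (1.3 - quality) * float(rng.uniform(0.4, 1.1))
    return nutrient_vector(amounts)


# --------------------------------------------------------------------------
# packaged fixtures
# --------------------------------------------------------------------------

def _t1_table() -> pd.DataFrame:
    ref = resources.files("mealopt.data") / "t1_breakfast.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col="category_id")


def fixture_t1_breakfast(population: str) -> BreakfastPattern:
    """Packaged observed bottom-tertile (T1) mean breakfast, grams per
    category, for ``"children"`` or ``"adults"``."""
    if population not in ("children", "adults"):
        raise ValueError(f"unknown population {population!r}")
    table = _t1_table()
    return BreakfastPattern(
        table[f"{population}_t1_g"].astype(float).rename(None),
        population=population,
        provenance="observed-T1",
    )


def fixture_calcium_example() -> tuple[CompositionMatrix, BreakfastPattern, GuidelineSet]:
    """The two-food calcium problem contrasting the LP objectives.

    One serving of milk (250 g) and one of cheese (30 g) provide 480 mg of
    calcium; the breakfast target is 510 mg.  The calcium densities —
    milk 120 mg/100 g, cheese 600 mg/100 g — are the unique pair consistent
    with the four stated quantities: the 480 mg baseline and the fact that
    either +25 g of milk or +5 g of cheese closes the 30 mg gap.  The
    relative objective raises milk to 275 g (distance 0.1 beats the 17 %
    cheese increase); the absolute objective raises cheese by 5 g
    (5 g beats 25 g of milk).
    """
    density = pd.DataFrame(
        {
            "energy_kcal": {"milk": 48.0, "cheese": 290.0},
            "calcium_mg": {"milk": 120.0, "cheese": 600.0},
        }
    ).loc[["milk", "cheese"]]
    composition = CompositionMatrix(density)
    pattern = BreakfastPattern(
        pd.Series({"milk": 250.0, "cheese": 30.0}),
        population="adults",
        provenance="observed",
    )
    guidelines = GuidelineSet(
        [NutrientGuideline("calcium_mg", "absolute", "min", (510.0,), "both")],
        label="calcium-example",
    )
    return composition, pattern, guidelines


# --------------------------------------------------------------------------
# CSV dialects
# --------------------------------------------------------------------------

def write_population_csv(records: list[IntakeRecord], items_path, days_path=None) -> None:
    """Write records as a long item table (person_id, age_years, meal_label,
    category_id, grams) plus, optionally, a day-nutrient table."""
    rows = [
        (r.person_id, r.age_years, m.label, cid, grams)
        for r in records for m in r.meals for cid, grams in m.items
    ]
    pd.DataFrame(
        rows, columns=["person_id", "age_years", "meal_label", "category_id", "grams"]
    ).to_csv(items_path, index=False)
    if days_path is not None:
        day = pd.DataFrame(
            {r.person_id: r.day_nutrients for r in records}
        ).T
        ages = pd.Series({r.person_id: r.age_years for r in records}, name="age_years")
        pd.concat([ages, day], axis=1).rename_axis("person_id").to_csv(days_path)


def read_population_csv(items_path, days_path) -> list[IntakeRecord]:
    """Inverse of :func:`write_population_csv` (both files required)."""
    items = pd.read_csv(items_path)
    days = pd.read_csv(days_path, index_col="person_id")
    records = []
    for pid, sub in items.groupby("person_id", sort=True):
        meals = [
            Meal(label, list(zip(g["category_id"], g["grams"].astype(float))))
            for label, g in sub.groupby("meal_label", sort=False)
        ]
        row = days.loc[pid]
        day_vec = row.drop("age_years").astype(float)
        records.append(IntakeRecord(str(pid), int(row["age_years"]), meals, day_vec))
    return records
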