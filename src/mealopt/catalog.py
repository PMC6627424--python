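"""Food-category catalog.

Foods are aggregated into What We Eat in America (WWEIA) categories, the
granularity at which the optimization operates.  The default catalog holds
the 31 categories retained after dropping alcohol, baby foods/beverages,
condiments, water and unclassifiable items, grouped into ten super-groups
(Beverages, Fats & Oils, Fruit, Grains, Milk & Dairy, Mixed Dishes,
Protein Foods, Snacks & Sweets, Sugars, Vegetables).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FoodCategory:
    """One aggregate food category.

    Parameters
    ----------
    id : str
        Short stable key, unique within a catalog (e.g. ``"milk"``).
    display_name : str
        Human-readable WWEIA category name (e.g. ``"Milk"``).
    group : str
        Super-group the category belongs to (e.g. ``"Milk & Dairy"``).
    """

    id: str
    display_name: str
    group: str


# (id, display name, super-group) for the 31 WWEIA categories used in the
# breakfast analysis.  Order matters: it is the canonical column order of
# composition matrices and pattern tables.
_DEFAULT = [
    ("coffee_tea", "Coffee & Tea", "Beverages"),
    ("diet_beverages", "Diet Beverages", "Beverages"),
    ("sweetened_beverages", "Sweetened Beverages", "Beverages"),
    ("fats_oils", "Fats & Oils", "Fats & Oils"),
    ("fruit", "Fruit", "Fruit"),
    ("juice_100", "100% Juice", "Fruit"),
    ("breads", "Breads", "Grains"),
    ("cooked_grains", "Cooked grains", "Grains"),
    ("grains", "Grains", "Grains"),
    ("quick_breads", "Quick Breads", "Grains"),
    ("rte_cereal_high_sugar", "High Sugar RTE Cereal", "Grains"),
    ("rte_cereal_low_sugar", "Low Sugar RTE Cereal", "Grains"),
    ("cheese", "Cheese", "Milk & Dairy"),
    ("flavored_milk", "Flavored Milk", "Milk & Dairy"),
    ("milk", "Milk", "Milk & Dairy"),
    ("milk_dessert_drinks", "Milk Dessert Drinks", "Milk & Dairy"),
    ("yogurt", "Yogurt", "Milk & Dairy"),
    ("mixed_dishes", "Mixed Dishes", "Mixed Dishes"),
    ("eggs", "Eggs", "Protein Foods"),
    ("nuts_beans_soy", "Nuts, Beans & Soy", "Protein Foods"),
    ("processed_meat", "Processed Meat", "Protein Foods"),
    ("seafood_meat", "Seafood/Meat", "Protein Foods"),
    ("candy", "Candy", "Snacks & Sweets"),
    ("crackers", "Crackers", "Snacks & Sweets"),
    ("other_desserts", "Other Desserts", "Snacks & Sweets"),
    ("savory_snacks", "Savory Snacks", "Snacks & Sweets"),
    ("snack_meal_bars", "Snack/Meal Bars", "Snacks & Sweets"),
    ("sweet_bakery", "Sweet Bakery", "Snacks & Sweets"),
    ("sugars", "Sugars", "Sugars"),
    ("vegetables_nonpotato", "Vegetables, Non-potato", "Vegetables"),
    ("white_potatoes", "White Potatoes", "Vegetables"),
]


def default_catalog() -> list[FoodCategory]:
    """Return the 31-category WWEIA breakfast catalog, in canonical order."""
    return [FoodCategory(i, n, g) for i, n, g in _DEFAULT]


def catalog_ids() -> list[str]:
    """Canonical ordered category ids of the default catalog."""
    return [i for i, _, _ in _DEFAULT]


def by_id(category_id: str) -> FoodCategory:
    """Look up a default-catalog category by id.

    Raises
    ------
    KeyError
        If ``category_id`` is not in the default catalog.
    """
    for i, n, g in _DEFAULT:
        if i == category_id:
            return FoodCategory(i, n, g)
    raise KeyError(f"unknown food category: {category_id!r}")
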