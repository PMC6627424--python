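"""Nutrient registry and the food-composition matrix.

A :class:`CompositionMatrix` stores the nutrient density of each food
category per 100 g of food.  It is the coefficient source of every linear
constraint and of every pattern-to-nutrient conversion in the package.

Nutrient amounts use fixed conventional units, encoded in the key suffix:
kcal for energy, g for macronutrients / fiber / added sugar, mg for
sodium, calcium, iron, potassium, magnesium, zinc, vitamin C and the
B-vitamins thiamin/riboflavin/niacin/B6, and µg for vitamins A (RAE),
D, B12 and folate.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical nutrient keys, in display order (unit embedded in the suffix).
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "carbohydrate_g",
    "fat_g",
    "sfa_g",
    "mufa_g",
    "pufa_g",
    "added_sugar_g",
    "fiber_g",
    "sodium_mg",
    "calcium_mg",
    "iron_mg",
    "potassium_mg",
    "magnesium_mg",
    "zinc_mg",
    "vitamin_a_ug",
    "vitamin_c_mg",
    "vitamin_d_ug",
    "thiamin_mg",
    "riboflavin_mg",
    "niacin_mg",
    "vitamin_b6_mg",
    "vitamin_b12_ug",
    "folate_ug",
)

#: Energy-conversion (Atwater) factors, kcal per gram, for nutrients that
#: carry energy.  Used to linearize percent-of-energy guidelines.
ATWATER_KCAL_PER_G: dict[str, float] = {
    "protein_g": 4.0,
    "carbohydrate_g": 4.0,
    "added_sugar_g": 4.0,
    "fat_g": 9.0,
    "sfa_g": 9.0,
    "mufa_g": 9.0,
    "pufa_g": 9.0,
}

# A NutrientVector is a pandas Series mapping nutrient key -> amount, in the
# units above; it must carry "energy_kcal" whenever a score or percent-energy
# computation is requested.
NutrientVector = pd.Series


def nutrient_vector(amounts: Mapping[str, float]) -> NutrientVector:
    """Build a nutrient vector over the canonical nutrient set.

    Missing nutrients are filled with zero; unknown keys raise.
    """
    unknown = set(amounts) - set(NUTRIENTS)
    if unknown:
        raise KeyError(f"unknown nutrient keys: {sorted(unknown)}")
    vec = pd.Series(0.0, index=list(NUTRIENTS))
    for key, val in amounts.items():
        vec[key] = float(val)
    return vec


class CompositionMatrix:
    """Nutrient density per 100 g for each food category.

    Parameters
    ----------
    density : pandas.DataFrame
        Rows indexed by category id, columns nutrient keys, values the
        amount of nutrient per 100 g of the category.  All values must be
        nonnegative.
    """

    def __init__(self, density: pd.DataFrame):
        if (density.values < 0).any():
            bad = density.columns[(density.values < 0).any(axis=0)].tolist()
            raise ValueError(f"negative nutrient densities in columns {bad}")
        if density.index.has_duplicates:
            raise ValueError("duplicate category ids in composition matrix")
        self.density = density.astype(float).rename_axis("category_id")

    @property
    def categories(self) -> list[str]:
        return list(self.density.index)

    @property
    def nutrients(self) -> list[str]:
        return list(self.density.columns)

    def require_nutrients(self, needed: Iterable[str]) -> None:
        """Validate that every nutrient in ``needed`` has a column.

        Raises ``KeyError`` naming the missing nutrients; used when a
        guideline set or scoring parameterization is bound to this matrix.
        """
        missing = sorted(set(needed) - set(self.density.columns))
        if missing:
            raise KeyError(f"composition matrix lacks nutrients: {missing}")

    def nutrients_of(self, quantities: Mapping[str, float] | pd.Series) -> NutrientVector:
        """Total nutrients of a {category: grams} mixture (grams x density / 100)."""
        q = pd.Series(quantities, dtype=float)
        missing = sorted(set(q.index) - set(self.density.index))
        if missing:
            raise KeyError(f"categories absent from composition matrix: {missing}")
        sub = self.density.loc[q.index]
        return sub.mul(q, axis=0).sum(axis=0) / 100.0

    def to_csv(self, path) -> None:
        """Write as CSV with a leading ``category_id`` column."""
        self.density.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CompositionMatrix":
        return cls(pd.read_csv(path, index_col="category_id"))

    def __eq__(self, other) -> bool:
        return isinstance(other, CompositionMatrix) and self.density.equals(other.density)

    def __repr__(self) -> str:
        return (
            f"<CompositionMatrix {len(self.categories)} categories x "
            f"{len(self.nutrients)} nutrients>"
        )


def assert_close(a: NutrientVector, b: NutrientVector, tol: float = 1e-9) -> None:
    """Raise AssertionError unless two nutrient vectors agree within ``tol``."""
    a, b = a.align(b, fill_value=0.0)
    if not np.allclose(a.values, b.values, rtol=tol, atol=tol):
        raise AssertionError(f"nutrient vectors differ:\n{a}\n{b}")
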