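"""Individual intake records from a 24-hour dietary recall.

A record holds the self-reported eating episodes of one respondent for one
day — each episode a labelled meal with (category, grams) items — plus the
whole-day nutrient totals used for diet-quality scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composition import NutrientVector

CHILD_MAX_AGE = 17  # ages 6-17 are "children"; 18+ are "adults"


def age_group_of(age_years: int) -> str:
    if age_years < 6:
        raise ValueError(f"age {age_years} below the study minimum of 6 years")
    return "children" if age_years <= CHILD_MAX_AGE else "adults"


@dataclass
class Meal:
    """One labelled eating episode: a meal name and its food items."""

    label: str
    items: list[tuple[str, float]] = field(default_factory=list)  # (category_id, grams)

    def __post_init__(self):
        for cat, grams in self.items:
            if grams < 0:
                raise ValueError(f"negative grams for {cat!r} in meal {self.label!r}")


@dataclass
class IntakeRecord:
    """One respondent-day of dietary intake.

    ``day_nutrients`` is the full-day nutrient vector (all meals plus any
    foods outside the listed episodes); it must have positive energy for
    the record to be scoreable.
    """

    person_id: str
    age_years: int
    meals: list[Meal]
    day_nutrients: NutrientVector

    @property
    def age_group(self) -> str:
        return age_group_of(self.age_years)


def records_to_frame(records: list[IntakeRecord]) -> pd.DataFrame:
    """Flatten meal items to a long table (person_id, meal_label, category_id, grams)."""
    rows = [
        (r.person_id, m.label, cat, grams)
        for r in records
        for m in r.meals
        for cat, grams in m.items
    ]
    return pd.DataFrame(rows, columns=["person_id", "meal_label", "category_id", "grams"])
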