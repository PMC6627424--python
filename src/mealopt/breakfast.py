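"""Breakfast identification and meal-pattern arithmetic.

Breakfast is taken from self-report: every eating episode labelled
"breakfast", "desayuno" or "brunch" (case-insensitive, configurable)
is pooled into a single morning meal.  Respondents whose pooled morning
intake provides less than 50 kcal — or who report no such episode — are
breakfast *skippers* and are excluded from all downstream analysis.
An episode of exactly 50 kcal counts as a consumer (the skipper rule is
a strict "< 50 kcal").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .composition import CompositionMatrix, NutrientVector
from .records import IntakeRecord

#: Meal labels treated as breakfast, matched case-insensitively.
BREAKFAST_LABELS = frozenset({"breakfast", "desayuno", "brunch"})

#: Minimum pooled energy (kcal) for a morning meal to count as a breakfast.
ENERGY_THRESHOLD_KCAL = 50.0


@dataclass
class BreakfastPattern:
    """Grams per food category for one (or one mean) breakfast.

    ``provenance`` records where the pattern came from, e.g. "observed-T1"
    or "optimized-relative"; ``population`` is "children" or "adults"
    (or None for a single person's meal).
    """

    quantities: pd.Series  # category_id -> grams
    population: str | None = None
    provenance: str | None = None

    def __post_init__(self):
        self.quantities = pd.Series(self.quantities, dtype=float)
        if (self.quantities < 0).any():
            bad = self.quantities[self.quantities < 0].index.tolist()
            raise ValueError(f"negative gram quantities for {bad}")

    @property
    def categories(self) -> list[str]:
        return list(self.quantities.index)

    def total_grams(self) -> float:
        return float(self.quantities.sum())

    def to_csv(self, path) -> None:
        self.quantities.rename("grams").rename_axis("category_id").to_csv(path)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BreakfastPattern":
        q = pd.read_csv(path, index_col="category_id")["grams"]
        return cls(q, **kwargs)


def extract_breakfast(
    record: IntakeRecord,
    composition: CompositionMatrix,
    energy_threshold: float = ENERGY_THRESHOLD_KCAL,
    labels: frozenset[str] = BREAKFAST_LABELS,
) -> BreakfastPattern | None:
    """Pool a record's breakfast-labelled episodes into one pattern.

    Returns ``None`` when the record is a skipper: no breakfast-labelled
    meal, or pooled energy strictly below ``energy_threshold``.
    """
    wanted = {l.lower() for l in labels}
    grams: dict[str, float] = {}
    found = False
    for meal in record.meals:
        if meal.label.lower() not in wanted:
            continue
        found = True
        for cat, g in meal.items:
            grams[cat] = grams.get(cat, 0.0) + g
    if not found:
        return None
    quantities = pd.Series(grams, dtype=float)
    energy = float(composition.nutrients_of(quantities).get("energy_kcal", 0.0))
    if energy < energy_threshold:
        return None
    return BreakfastPattern(quantities, population=record.age_group, provenance="observed")


def mean_pattern(patterns: list[BreakfastPattern], provenance: str | None = None) -> BreakfastPattern:
    """Per-category arithmetic mean over breakfast consumers.

    Categories absent from a pattern count as 0 g for that person.  All
    patterns must carry the same population label.
    """
    if not patterns:
        raise ValueError("mean_pattern needs at least one pattern")
    populations = {p.population for p in patterns}
    if len(populations) > 1:
        raise ValueError(f"mixed populations in mean_pattern: {sorted(map(str, populations))}")
    frame = pd.concat([p.quantities for p in patterns], axis=1).fillna(0.0)
    return BreakfastPattern(
        frame.mean(axis=1), population=populations.pop(), provenance=provenance
    )


def pattern_nutrients(pattern: BreakfastPattern, composition: CompositionMatrix) -> NutrientVector:
    """Nutrient totals of a pattern: sum over categories of grams x density / 100."""
    return composition.nutrients_of(pattern.quantities)


@dataclass
class BreakfastExtraction:
    """Result of running the skipper rule over a population."""

    consumers: list[BreakfastPattern] = field(default_factory=list)
    consumer_ids: list[str] = field(default_factory=list)
    skipper_ids: list[str] = field(default_factory=list)

    @property
    def n_skippers(self) -> int:
        return len(self.skipper_ids)


def extract_population(
    records: list[IntakeRecord],
    composition: CompositionMatrix,
    energy_threshold: float = ENERGY_THRESHOLD_KCAL,
) -> BreakfastExtraction:
    """Apply :func:`extract_breakfast` to every record, splitting consumers
    from skippers."""
    out = BreakfastExtraction()
    for rec in records:
        pattern = extract_breakfast(rec, composition, energy_threshold)
        if pattern is None:
            out.skipper_ids.append(rec.person_id)
        else:
            out.consumers.append(pattern)
            out.consumer_ids.append(rec.person_id)
    return out
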