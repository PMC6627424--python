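"""NRF9.3 nutrient-density scoring and diet-quality tertiles.

The Nutrient Rich Food index NRF9.3 summarizes whole-day diet quality as

    NRF9.3 = (NR - LIM) x 100

where NR sums, over 9 qualifying nutrients, the percent of the daily value
(DV) provided per 2000 kcal, each percent truncated at 100 so that excess
of one nutrient cannot compensate for inadequacy of another; and LIM sums,
over 3 limiting nutrients (added sugar, saturated fat, sodium), only the
share in excess of the maximum recommended value (MRV), again per
2000 kcal.  The score therefore lives on a 0-900 scale at the top end
(all DVs met, no MRV exceeded) and is unbounded below.

Working in capped *fractions* (ratio of 1 = 100 %DV) and scaling the
difference by 100 gives the same 0-900 scale as capping percentages at
100 and summing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .composition import NutrientVector

#: Daily values for the 9 qualifying nutrients (amount per day).
DEFAULT_DV = {
    "protein_g": 50.0,
    "fiber_g": 28.0,
    "vitamin_a_ug": 900.0,
    "vitamin_c_mg": 90.0,
    "vitamin_d_ug": 20.0,
    "calcium_mg": 1300.0,
    "iron_mg": 18.0,
    "potassium_mg": 4700.0,
    "magnesium_mg": 420.0,
}

#: Maximum recommended values for the 3 limiting nutrients.
DEFAULT_MRV = {
    "added_sugar_g": 50.0,
    "sfa_g": 20.0,
    "sodium_mg": 2300.0,
}


@dataclass(frozen=True)
class NRFParameters:
    """Reference amounts and capping rules for the NRF9.3 score.

    The default parameterization uses vitamin D (a nutrient of public
    health concern) among the qualifying nutrients in place of vitamin E.
    """

    qualifying: dict[str, float]
    limiting: dict[str, float]
    energy_basis_kcal: float = 2000.0
    cap_percent: float = 100.0

    def __post_init__(self):
        if any(v <= 0 for v in self.qualifying.values()):
            raise ValueError("qualifying reference values must be positive")
        if any(v <= 0 for v in self.limiting.values()):
            raise ValueError("limiting reference values must be positive")

    @classmethod
    def default(cls) -> "NRFParameters":
        return cls(qualifying=dict(DEFAULT_DV), limiting=dict(DEFAULT_MRV))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NRFParameters":
        """Load from a YAML mapping with keys qualifying, limiting and
        optionally energy_basis_kcal / cap_percent."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = cls(qualifying=dict(raw["qualifying"]), limiting=dict(raw["limiting"]))
        extras = {k: raw[k] for k in ("energy_basis_kcal", "cap_percent") if k in raw}
        return replace(base, **extras) if extras else base


def _adjusted(intake: NutrientVector, nutrient: str, params: NRFParameters) -> float:
    energy = float(intake.get("energy_kcal", 0.0))
    if energy <= 0:
        raise ValueError("intake energy must be positive for NRF scoring")
    if nutrient not in intake.index:
        raise KeyError(f"intake vector is missing nutrient {nutrient!r}")
    return float(intake[nutrient]) * params.energy_basis_kcal / energy


def compute_nr(intake: NutrientVector, params: NRFParameters | None = None) -> float:
    """Qualifying-nutrient subscore: sum of capped DV fractions per 2000 kcal.

    Each term is min(intake_i * 2000/energy / DV_i, cap) with cap = 1 at
    the default 100 % truncation, so the sum lies in [0, 9].
    """
    params = params or NRFParameters.default()
    cap = params.cap_percent / 100.0
    return sum(
        min(_adjusted(intake, nut, params) / dv, cap)
        for nut, dv in params.qualifying.items()
    )


def compute_lim(intake: NutrientVector, params: NRFParameters | None = None) -> float:
    """Limiting-nutrient subscore: per-nutrient excess over the MRV.

    Each term is max(intake_i * 2000/energy / MRV_i - 1, 0); only the
    share in excess of the recommended amount counts, per nutrient.
    """
    params = params or NRFParameters.default()
    return sum(
        max(_adjusted(intake, nut, params) / mrv - 1.0, 0.0)
        for nut, mrv in params.limiting.items()
    )


def compute_nrf93(intake: NutrientVector, params: NRFParameters | None = None) -> float:
    """NRF9.3 = (NR - LIM) x 100; at most 900 under default parameters."""
    params = params or NRFParameters.default()
    return (compute_nr(intake, params) - compute_lim(intake, params)) * 100.0


@dataclass
class ScoredPerson:
    """A scored respondent: subscores, NRF9.3 and (once assigned) tertile."""

    person_id: str
    age_group: str
    nr: float
    lim: float
    nrf93: float
    tertile: str | None = None


def score_person(person_id: str, age_group: str, intake: NutrientVector,
                 params: NRFParameters | None = None) -> ScoredPerson:
    params = params or NRFParameters.default()
    nr = compute_nr(intake, params)
    lim = compute_lim(intake, params)
    return ScoredPerson(person_id, age_group, nr, lim, (nr - lim) * 100.0)


def assign_tertiles(people: list[ScoredPerson]) -> list[ScoredPerson]:
    """Assign age-group-specific diet-quality tertiles T1 < T2 < T3.

    Within each age group, people are ranked by NRF9.3 (ties broken by
    person_id for reproducibility) and split into thirds: the lowest third
    is T1, the top third T3.  When the group size is not divisible by 3
    the extra members go to the lower tertiles first, so sizes differ by
    at most one.  Returns the same ScoredPerson objects with ``tertile``
    set; the input list order is preserved.
    """
    if not people:
        raise ValueError("cannot assign tertiles to an empty population")
    groups: dict[str, list[ScoredPerson]] = {}
    for p in people:
        groups.setdefault(p.age_group, []).append(p)
    for group, members in groups.items():
        if len(members) < 3:
            raise ValueError(
                f"age group {group!r} has {len(members)} members; need >= 3 for tertiles"
            )
        ranked = sorted(members, key=lambda p: (p.nrf93, p.person_id))
        n = len(ranked)
        base, rem = divmod(n, 3)
        sizes = [base + (1 if i < rem else 0) for i in range(3)]  # extras to T1 first
        start = 0
        for label, size in zip(("T1", "T2", "T3"), sizes):
            for p in ranked[start:start + size]:
                p.tertile = label
            start += size
    return people
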