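"""Nutrient guidelines and their compilation to linear constraints.

A :class:`GuidelineSet` holds per-nutrient bounds for a meal — absolute
amounts (e.g. sodium at most 460 mg) or percent-of-energy bounds (e.g.
saturated fat below 10 %E).  :func:`compile_constraints` turns a guideline
set plus a composition matrix into a :class:`LinearConstraintSystem` over
food-category gram quantities, the form the LP solver consumes.

Percent-of-energy guidelines are linearized with Atwater factors
(4 kcal/g for carbohydrate, protein and added sugar; 9 kcal/g for fats):
"nutrient below p %E" becomes

    sum_c x_c * (f * density_nut,c - (p/100) * density_energy,c) / 100 <= 0.

All bounds are compiled as non-strict inequalities even where a source
prints them as strict; linear programming needs closed feasible sets, and
binding optima then sit exactly on the printed bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .composition import ATWATER_KCAL_PER_G, CompositionMatrix, NutrientVector

POPULATIONS = ("children", "adults")


@dataclass(frozen=True)
class NutrientGuideline:
    """One bound on one nutrient for one population (or both).

    ``values`` holds one number for min/max, two (low, high) for range.
    Percent-energy values are in percent of meal energy.
    """

    nutrient: str
    basis: str  # "absolute" | "percent_energy"
    bound: str  # "min" | "max" | "range"
    values: tuple[float, ...]
    population: str = "both"  # "children" | "adults" | "both"

    def __post_init__(self):
        if self.basis not in ("absolute", "percent_energy"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.bound not in ("min", "max", "range"):
            raise ValueError(f"unknown bound kind {self.bound!r}")
        expected = 2 if self.bound == "range" else 1
        if len(self.values) != expected:
            raise ValueError(
                f"{self.bound} guideline for {self.nutrient} needs "
                f"{expected} value(s), got {len(self.values)}"
            )
        if self.bound == "range" and not self.values[0] < self.values[1]:
            raise ValueError(f"range bounds must be ordered low < high: {self.values}")
        if self.basis == "percent_energy" and not all(0 < v <= 100 for v in self.values):
            raise ValueError(f"percent-energy values must lie in (0, 100]: {self.values}")
        if self.population not in POPULATIONS + ("both",):
            raise ValueError(f"unknown population {self.population!r}")

    def applies_to(self, population: str) -> bool:
        return self.population in ("both", population)

    def satisfied_by(self, nutrients: NutrientVector, tol: float = 1e-9) -> bool:
        """Direct (non-compiled) check of this guideline on a nutrient vector."""
        value = float(nutrients[self.nutrient])
        if self.basis == "percent_energy":
            energy = float(nutrients["energy_kcal"])
            if energy <= 0:
                return False
            value = 100.0 * value * ATWATER_KCAL_PER_G[self.nutrient] / energy
        scale = max(1.0, *(abs(v) for v in self.values))
        if self.bound == "min":
            return value >= self.values[0] - tol * scale
        if self.bound == "max":
            return value <= self.values[0] + tol * scale
        lo, hi = self.values
        return lo - tol * scale <= value <= hi + tol * scale


@dataclass
class GuidelineSet:
    """A labelled collection of nutrient guidelines."""

    guidelines: list[NutrientGuideline]
    label: str = ""

    def __post_init__(self):
        seen = set()
        for g in self.guidelines:
            pops = POPULATIONS if g.population == "both" else (g.population,)
            for pop in pops:
                key = (g.nutrient, g.basis, pop)
                if key in seen:
                    raise ValueError(
                        f"duplicate guideline for nutrient {g.nutrient!r}, population {pop!r}"
                    )
                seen.add(key)

    def for_population(self, population: str) -> list[NutrientGuideline]:
        if population not in POPULATIONS:
            raise ValueError(f"unknown population {population!r}")
        return [g for g in self.guidelines if g.applies_to(population)]

    @property
    def nutrients(self) -> set[str]:
        keys = {g.nutrient for g in self.guidelines}
        if any(g.basis == "percent_energy" for g in self.guidelines):
            keys.add("energy_kcal")
        return keys

    # -- YAML round trip ---------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "GuidelineSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "GuidelineSet":
        guidelines = [
            NutrientGuideline(
                nutrient=entry["nutrient"],
                basis=entry["basis"],
                bound=entry["bound"],
                values=tuple(float(v) for v in entry["values"]),
                population=entry.get("population", "both"),
            )
            for entry in raw["guidelines"]
        ]
        return cls(guidelines, label=raw.get("label", ""))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "label": self.label,
            "guidelines": [
                {
                    "nutrient": g.nutrient,
                    "basis": g.basis,
                    "bound": g.bound,
                    "values": list(g.values),
                    "population": g.population,
                }
                for g in self.guidelines
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def default_guidelines(population: str | None = None) -> GuidelineSet:
    """The packaged IBRI breakfast guideline set.

    With ``population`` given, returns only the guidelines applying to that
    population (paired entries resolved); otherwise the full set.
    """
    ref = resources.files("mealopt.data") / "ibri_guidelines.yaml"
    raw = yaml.safe_load(ref.read_text())
    full = GuidelineSet._from_mapping(raw)
    if population is None:
        return full
    return GuidelineSet(full.for_population(population), label=f"{full.label}-{population}")


@dataclass
class LinearConstraintSystem:
    """Linear inequality rows over food-category gram quantities.

    Each row i reads  ``coefficients[i] . x  {sense_i}  rhs[i]`` with sense
    "<=" or ">=", over ``x`` in grams per category; ``labels[i]`` traces the
    row to its source guideline (e.g. ``"sodium_mg:max"``).  Nonnegativity
    ``x >= 0`` is implicit and enforced by the solver.
    """

    categories: list[str]
    coefficients: np.ndarray  # (n_rows, n_categories)
    senses: list[str]
    rhs: np.ndarray
    labels: list[str]
    guideline_of: dict[str, NutrientGuideline] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def as_upper_bound(self) -> tuple[np.ndarray, np.ndarray]:
        """All rows converted to A x <= b form (>= rows negated)."""
        signs = np.array([1.0 if s == "<=" else -1.0 for s in self.senses])
        return self.coefficients * signs[:, None], self.rhs * signs

    def evaluate(self, quantities: pd.Series) -> np.ndarray:
        x = pd.Series(quantities, dtype=float).reindex(self.categories).fillna(0.0).values
        return self.coefficients @ x

    def violations(self, quantities: pd.Series) -> pd.Series:
        """Per-row violation amount (0 where satisfied), indexed by label."""
        vals = self.evaluate(quantities)
        out = np.where(
            np.array(self.senses) == "<=",
            np.maximum(vals - self.rhs, 0.0),
            np.maximum(self.rhs - vals, 0.0),
        )
        return pd.Series(out, index=self.labels)

    def satisfied(self, quantities: pd.Series, tol: float = 1e-9) -> bool:
        scale = np.maximum(1.0, np.abs(self.rhs))
        return bool((self.violations(quantities).values <= tol * scale).all())


def compile_constraints(
    guidelines: GuidelineSet,
    composition: CompositionMatrix,
    population: str,
) -> LinearConstraintSystem:
    """Compile a guideline set against a composition matrix.

    Absolute guidelines become one row (two for a range) of
    ``sum_c x_c * density/100 {>=,<=} value``; percent-of-energy guidelines
    are linearized with Atwater factors as described in the module
    docstring.  Every row label is ``"<nutrient>:<min|max>"``.
    """
    active = guidelines.for_population(population)
    if not active:
        raise ValueError(f"no guidelines for population {population!r}")
    needed = {g.nutrient for g in active}
    if any(g.basis == "percent_energy" for g in active):
        needed.add("energy_kcal")
    composition.require_nutrients(needed)

    cats = composition.categories
    dens = composition.density
    rows, senses, rhs, labels = [], [], [], []
    guideline_of: dict[str, NutrientGuideline] = {}

    def add(g: NutrientGuideline, coeffs: np.ndarray, sense: str, value: float, kind: str):
        label = f"{g.nutrient}:{kind}"
        rows.append(coeffs)
        senses.append(sense)
        rhs.append(value)
        labels.append(label)
        guideline_of[label] = g

    for g in active:
        if g.basis == "absolute":
            coeffs = dens[g.nutrient].values / 100.0
            if g.bound == "min":
                add(g, coeffs, ">=", g.values[0], "min")
            elif g.bound == "max":
                add(g, coeffs, "<=", g.values[0], "max")
            else:
                add(g, coeffs, ">=", g.values[0], "min")
                add(g, coeffs, "<=", g.values[1], "max")
        else:  # percent_energy: f*nut - (p/100)*energy {<=,>=} 0
            factor = ATWATER_KCAL_PER_G[g.nutrient]
            energy = dens["energy_kcal"].values
            nut = dens[g.nutrient].values

            def pe_coeffs(pct: float) -> np.ndarray:
                return (factor * nut - (pct / 100.0) * energy) / 100.0

            if g.bound == "min":
                add(g, pe_coeffs(g.values[0]), ">=", 0.0, "min")
            elif g.bound == "max":
                add(g, pe_coeffs(g.values[0]), "<=", 0.0, "max")
            else:
                add(g, pe_coeffs(g.values[0]), ">=", 0.0, "min")
                add(g, pe_coeffs(g.values[1]), "<=", 0.0, "max")

    return LinearConstraintSystem(
        categories=list(cats),
        coefficients=np.vstack(rows),
        senses=senses,
        rhs=np.asarray(rhs, dtype=float),
        labels=labels,
        guideline_of=guideline_of,
    )
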