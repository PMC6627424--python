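"""Observed-vs-optimized comparison reports and tertile summaries.

The :class:`ComparisonReport` mirrors the two tables a meal-optimization
analysis ends with: grams per food category (observed, both optimized
patterns, deltas) and nutrients per guideline row (observed, optimized,
bound, pass / binding flags).  Reports serialize deterministically to CSV
and JSON; display formatting rounds to one decimal while machine output
keeps full precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .breakfast import BreakfastPattern, pattern_nutrients
from .composition import CompositionMatrix
from .guidelines import GuidelineSet, NutrientGuideline, compile_constraints
from .optimize import BINDING_TOL, LPSolution


def _guideline_text(g: NutrientGuideline) -> str:
    if g.bound == "min":
        body = f">{g.values[0]:g}"
    elif g.bound == "max":
        body = f"<{g.values[0]:g}"
    else:
        body = f"({g.values[0]:g},{g.values[1]:g})"
    return body + (" %E" if g.basis == "percent_energy" else "")


def _nutrient_value(nutrients: pd.Series, g: NutrientGuideline) -> float:
    from .composition import ATWATER_KCAL_PER_G

    value = float(nutrients[g.nutrient])
    if g.basis == "percent_energy":
        energy = float(nutrients["energy_kcal"])
        value = 100.0 * value * ATWATER_KCAL_PER_G[g.nutrient] / energy if energy > 0 else np.nan
    return value


def _flag(value: float, g: NutrientGuideline) -> str:
    bounds = g.values
    binding = any(abs(value - b) <= max(BINDING_TOL, 1e-9 * abs(b)) for b in bounds)
    if binding:
        return "binding"
    if g.bound == "min":
        ok = value >= bounds[0]
    elif g.bound == "max":
        ok = value <= bounds[0]
    else:
        ok = bounds[0] <= value <= bounds[1]
    return "pass" if ok else "fail"


@dataclass
class ComparisonReport:
    """Per-category and per-nutrient observed-vs-optimized tables."""

    category_table: pd.DataFrame
    nutrient_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    infeasible: pd.Series | None = None

    @property
    def n_failures(self) -> int:
        """Guideline failures among the *optimized* patterns (the observed
        column is expected to fail — that is why it is being optimized)."""
        cols = [c for c in ("relative_flag", "absolute_flag")
                if c in self.nutrient_table.columns]
        return int((self.nutrient_table[cols] == "fail").sum().sum()) if cols else 0

    def to_csv(self, category_path, nutrient_path) -> None:
        self.category_table.to_csv(category_path)
        self.nutrient_table.to_csv(nutrient_path)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metadata": self.metadata,
            "categories": json.loads(self.category_table.to_json(orient="index")),
            "nutrients": json.loads(self.nutrient_table.to_json(orient="index")),
        }
        if self.infeasible is not None:
            payload["infeasible_rows"] = self.infeasible.to_dict()
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def render(self) -> str:
        """One-decimal display rendering of both tables."""
        parts = [self.category_table.round(1).to_string(),
                 "",
                 self.nutrient_table.round(1).to_string()]
        return "\n".join(parts)


def build_report(
    t1: BreakfastPattern,
    solutions: tuple[LPSolution, LPSolution],
    composition: CompositionMatrix,
    guidelines: GuidelineSet,
) -> ComparisonReport:
    """Assemble the comparison report from (relative, absolute) solutions.

    If either solution is not optimal the report carries the infeasibility
    diagnostics instead of the tables.
    """
    relative, absolute = solutions
    meta = {
        "population": t1.population,
        "guideline_label": guidelines.label,
        "status_relative": relative.status,
        "status_absolute": absolute.status,
        "guidelines_hash": _guidelines_hash(guidelines),
    }
    if not (relative.success and absolute.success):
        diag = pd.concat(
            [s.diagnostics for s in (relative, absolute) if s.diagnostics is not None]
        )
        diag = diag.groupby(diag.index).max().sort_values(ascending=False)
        return ComparisonReport(pd.DataFrame(), pd.DataFrame(), meta, infeasible=diag)

    cats = sorted(
        set(t1.categories)
        | set(relative.optimized.categories)
        | set(absolute.optimized.categories)
    )
    obs = t1.quantities.reindex(cats).fillna(0.0)
    rel = relative.optimized.quantities.reindex(cats).fillna(0.0)
    ab = absolute.optimized.quantities.reindex(cats).fillna(0.0)
    category_table = pd.DataFrame(
        {
            "observed_g": obs,
            "optimized_relative_g": rel,
            "optimized_absolute_g": ab,
            "delta_relative_g": rel - obs,
            "delta_absolute_g": ab - obs,
        }
    ).rename_axis("category_id")

    population = t1.population or "adults"
    active = guidelines.for_population(population)
    obs_nut = pattern_nutrients(t1, composition)
    rel_nut = pattern_nutrients(relative.optimized, composition)
    ab_nut = pattern_nutrients(absolute.optimized, composition)
    rows = {}
    for g in active:
        key = f"{g.nutrient}" + (":%E" if g.basis == "percent_energy" else "")
        vo, vr, va = (_nutrient_value(n, g) for n in (obs_nut, rel_nut, ab_nut))
        rows[key] = {
            "observed": vo,
            "optimized_relative": vr,
            "optimized_absolute": va,
            "guideline": _guideline_text(g),
            "observed_flag": _flag(vo, g),
            "relative_flag": _flag(vr, g),
            "absolute_flag": _flag(va, g),
        }
    nutrient_table = pd.DataFrame.from_dict(rows, orient="index").rename_axis("nutrient")
    return ComparisonReport(category_table, nutrient_table, meta)


def tertile_composition(
    patterns_by_tertile: dict[str, list[BreakfastPattern]]
) -> pd.DataFrame:
    """Mean grams per category for each tertile (columns T1, T2, T3...).

    Input order within a tertile does not affect the result.
    """
    cols = {}
    for tertile in sorted(patterns_by_tertile):
        patterns = patterns_by_tertile[tertile]
        if not patterns:
            raise ValueError(f"tertile {tertile!r} has no patterns")
        frame = pd.concat([p.quantities for p in patterns], axis=1).fillna(0.0)
        cols[tertile] = frame.mean(axis=1)
    table = pd.DataFrame(cols).fillna(0.0).sort_index().rename_axis("category_id")
    return table


def _guidelines_hash(guidelines: GuidelineSet) -> str:
    blob = json.dumps(
        [
            (g.nutrient, g.basis, g.bound, list(g.values), g.population)
            for g in guidelines.guidelines
        ],
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_log(report: ComparisonReport, solutions: tuple[LPSolution, LPSolution],
            seed: int | None = None) -> str:
    """Plain-text run summary: seeds, guideline hash, status, binding rows."""
    relative, absolute = solutions
    lines = [
        f"population: {report.metadata.get('population')}",
        f"seed: {seed}",
        f"guidelines: {report.metadata.get('guideline_label')} "
        f"[{report.metadata.get('guidelines_hash')}]",
        f"relative: status={relative.status}"
        + (f" distance={relative.distance:.6f} binding={sorted(relative.binding)}"
           if relative.success else ""),
        f"absolute: status={absolute.status}"
        + (f" distance={absolute.distance:.6f} binding={sorted(absolute.binding)}"
           if absolute.success else ""),
    ]
    return "\n".join(lines)
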