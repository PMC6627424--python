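"""Deviation-minimizing linear programs over meal patterns.

Given an observed meal pattern (grams per food category) and a compiled
linear constraint system, the model finds the pattern that satisfies every
constraint while deviating least from the observed one.  Two objectives
are supported:

absolute
    min D = sum_i |x_i - obs_i|          (D in grams)
relative
    min D = sum_i |x_i - obs_i| / obs_i  (D unitless)

The absolute objective changes whichever foods close the nutrient gaps
with the fewest total grams; the relative objective prefers proportional
changes to foods already eaten in quantity and never introduces foods
that are not eaten at all (categories observed at 0 g are held at 0,
where the relative deviation is undefined).

Both objectives are exact LPs after the standard split of each deviation
into nonnegative parts: x_i = obs_i + p_i - n_i with p_i, n_i >= 0 and
objective sum w_i (p_i + n_i); at any optimum p_i * n_i = 0.

The public surface follows the model/results idiom: build a
:class:`DeviationLP` (or use :func:`solve_absolute` / :func:`solve_relative`),
call :meth:`DeviationLP.fit`, and read the returned :class:`LPSolution`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .breakfast import BreakfastPattern, pattern_nutrients
from .composition import CompositionMatrix
from .guidelines import GuidelineSet, LinearConstraintSystem, compile_constraints, default_guidelines

#: Absolute feasibility/optimality tolerance passed to the solver.
SOLVER_TOL = 1e-8
#: A constraint row is flagged binding when |row . x - rhs| <= this.
BINDING_TOL = 1e-6


@dataclass
class LPSolution:
    """Result of a fitted deviation LP.

    Attributes
    ----------
    optimized : BreakfastPattern or None
        The guideline-compliant pattern (None when infeasible).
    distance : float or None
        Objective value D — grams for the absolute objective, unitless
        for the relative one.
    status : str
        "optimal", "infeasible" or "unbounded".
    binding : list of str
        Labels of constraint rows with zero slack at the optimum.
    per_category_change : pandas.DataFrame
        Columns observed_g, optimized_g, delta_g, relative_delta.
    diagnostics : pandas.Series
        On infeasibility: per-row violation of the constraints at the
        observed pattern, most violated first (the rows that no feasible
        pattern can repair are among these).
    """

    objective: str
    observed: BreakfastPattern
    status: str
    optimized: BreakfastPattern | None = None
    distance: float | None = None
    binding: list[str] = field(default_factory=list)
    slack: pd.Series | None = None
    per_category_change: pd.DataFrame | None = None
    diagnostics: pd.Series | None = None

    @property
    def success(self) -> bool:
        return self.status == "optimal"

    def nutrients(self, composition: CompositionMatrix):
        """Nutrient vector of the optimized pattern."""
        if self.optimized is None:
            raise ValueError(f"no optimized pattern (status={self.status})")
        return pattern_nutrients(self.optimized, composition)

    def summary(self) -> str:
        """Human-readable account of the fit."""
        lines = [
            f"Deviation LP ({self.objective} objective)",
            f"  status:   {self.status}",
        ]
        if self.success:
            unit = "g" if self.objective == "absolute" else ""
            lines.append(f"  distance: {self.distance:.4f}{unit and ' ' + unit}")
            lines.append(f"  binding:  {', '.join(self.binding) or '(none)'}")
            moved = self.per_category_change[
                self.per_category_change["delta_g"].abs() > 1e-9
            ]
            lines.append(f"  categories changed: {len(moved)}")
            for cat, row in moved.iterrows():
                lines.append(
                    f"    {cat:<24s} {row.observed_g:8.1f} -> {row.optimized_g:8.1f} g"
                )
        else:
            lines.append("  most violated guideline rows at the observed pattern:")
            diag = self.diagnostics if self.diagnostics is not None else pd.Series(dtype=float)
            for label, v in diag.head(5).items():
                lines.append(f"    {label:<24s} violation {v:.3f}")
        return "\n".join(lines)


class DeviationLP:
    """Deviation-minimizing LP over one observed meal pattern.

    Parameters
    ----------
    observed : BreakfastPattern
        The pattern to stay close to; its categories define the variables.
    constraints : LinearConstraintSystem
        Compiled guideline rows (see :func:`mealopt.guidelines.compile_constraints`).
        Every constraint category must appear in the observed pattern.
    objective : {"relative", "absolute"}
    fixed_categories : iterable of str, optional
        Categories held exactly at their observed quantity.
    """

    def __init__(
        self,
        observed: BreakfastPattern,
        constraints: LinearConstraintSystem,
        objective: str = "relative",
        fixed_categories: tuple[str, ...] = (),
    ):
        if objective not in ("relative", "absolute"):
            raise ValueError(f"unknown objective {objective!r}")
        missing = set(constraints.categories) - set(observed.categories)
        if missing:
            raise ValueError(
                f"observed pattern lacks constraint categories: {sorted(missing)}"
            )
        unknown_fixed = set(fixed_categories) - set(observed.categories)
        if unknown_fixed:
            raise ValueError(f"fixed categories not in pattern: {sorted(unknown_fixed)}")
        self.observed = observed
        self.constraints = constraints
        self.objective = objective
        self.fixed_categories = tuple(fixed_categories)

    @classmethod
    def from_guidelines(
        cls,
        observed: BreakfastPattern,
        composition: CompositionMatrix,
        guidelines: GuidelineSet,
        population: str,
        **kwargs,
    ) -> "DeviationLP":
        """Compile ``guidelines`` for ``population`` and build the model."""
        system = compile_constraints(guidelines, composition, population)
        return cls(observed, system, **kwargs)

    # -- weights -----------------------------------------------------------
    def _weights_and_fixed(self) -> tuple[np.ndarray, np.ndarray]:
        obs = self.observed.quantities.reindex(self.constraints.categories).fillna(0.0)
        fixed = np.array([c in self.fixed_categories for c in obs.index])
        if self.objective == "absolute":
            weights = np.ones(len(obs))
        else:
            # zero-observed foods cannot enter under the relative objective
            fixed = fixed | (obs.values == 0.0)
            with np.errstate(divide="ignore"):
                weights = np.where(obs.values > 0, 1.0 / np.where(obs.values > 0, obs.values, 1.0), 0.0)
        return weights, fixed

    def fit(self) -> LPSolution:
        """Solve the LP and return an :class:`LPSolution`."""
        cats = self.constraints.categories
        obs = self.observed.quantities.reindex(cats).fillna(0.0)
        m = len(cats)
        weights, fixed = self._weights_and_fixed()

        a_ub, b_ub = self.constraints.as_upper_bound()
        # variables: [x (m), p (m), n (m)]; x - p + n = obs
        A_ub = np.hstack([a_ub, np.zeros((a_ub.shape[0], 2 * m))])
        A_eq = np.hstack([np.eye(m), -np.eye(m), np.eye(m)])
        c = np.concatenate([np.zeros(m), weights, weights])
        bounds = []
        for i in range(m):
            bounds.append((obs.values[i], obs.values[i]) if fixed[i] else (0.0, None))
        bounds += [(0.0, 0.0) if fixed[i] else (0.0, None) for i in range(m)]  # p
        bounds += [(0.0, 0.0) if fixed[i] else (0.0, None) for i in range(m)]  # n

        res = linprog(
            c,
            A_ub=A_ub,
            b_ub=b_ub,
            A_eq=A_eq,
            b_eq=obs.values,
            bounds=bounds,
            method="highs",
            options={"presolve": True, "primal_feasibility_tolerance": SOLVER_TOL,
                     "dual_feasibility_tolerance": SOLVER_TOL},
        )

        if res.status == 2:  # infeasible
            diag = self.constraints.violations(obs).sort_values(ascending=False)
            return LPSolution(
                objective=self.objective,
                observed=self.observed,
                status="infeasible",
                diagnostics=diag[diag > 0],
            )
        if res.status == 3:
            return LPSolution(self.objective, self.observed, status="unbounded")
        if not res.success:
            raise RuntimeError(f"LP solver failed: {res.message}")

        x = np.maximum(res.x[:m], 0.0)
        x[np.abs(x) < 1e-12] = 0.0
        optimized = BreakfastPattern(
            pd.Series(x, index=cats),
            population=self.observed.population,
            provenance=f"optimized-{self.objective}",
        )
        # recompute the distance from the pattern itself (not the solver's
        # objective) so the reported value is exact for the returned x
        delta = x - obs.values
        distance = float(np.sum(weights * np.abs(delta)))
        row_vals = self.constraints.evaluate(optimized.quantities)
        slack = pd.Series(
            np.where(np.array(self.constraints.senses) == "<=",
                     self.constraints.rhs - row_vals,
                     row_vals - self.constraints.rhs),
            index=self.constraints.labels,
        )
        binding = [l for l, s in slack.items() if abs(s) <= BINDING_TOL]
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(obs.values > 0, delta / obs.values, np.nan)
        change = pd.DataFrame(
            {
                "observed_g": obs.values,
                "optimized_g": x,
                "delta_g": delta,
                "relative_delta": rel,
            },
            index=cats,
        )
        return LPSolution(
            objective=self.objective,
            observed=self.observed,
            status="optimal",
            optimized=optimized,
            distance=distance,
            binding=binding,
            slack=slack,
            per_category_change=change,
        )


# -- convenience functional surface ---------------------------------------

#: Alias kept for users thinking in problem terms rather than model terms.
LPProblem = DeviationLP


def solve_absolute(problem: DeviationLP) -> LPSolution:
    """Solve with the absolute (gram) deviation objective."""
    model = DeviationLP(
        problem.observed, problem.constraints, "absolute", problem.fixed_categories
    )
    return model.fit()


def solve_relative(problem: DeviationLP) -> LPSolution:
    """Solve with the relative (proportional) deviation objective."""
    model = DeviationLP(
        problem.observed, problem.constraints, "relative", problem.fixed_categories
    )
    return model.fit()


def optimize_t1(
    population: str,
    composition: CompositionMatrix,
    t1_pattern: BreakfastPattern,
    guidelines: GuidelineSet | None = None,
) -> tuple[LPSolution, LPSolution]:
    """Optimize a bottom-tertile mean breakfast under the default guidelines.

    Runs both objectives against ``default_guidelines(population)`` (or a
    caller-supplied set) and returns ``(relative, absolute)`` solutions —
    the pipeline's headline stage.
    """
    gset = guidelines if guidelines is not None else default_guidelines(population)
    system = compile_constraints(gset, composition, population)
    base = DeviationLP(t1_pattern, system)
    return solve_relative(base), solve_absolute(base)


#: Hard cap on grid points enumerated by the brute-force oracle.
_ORACLE_MAX_POINTS = 3_000_000


def brute_force_oracle(
    problem: DeviationLP, grid_step: float | None = None, max_free: int = 3
) -> LPSolution:
    """Exhaustive grid-search solution for small problems.

    Verification oracle, independent of the LP path: enumerates a regular
    grid over a box containing the feasible region — the box edges derived
    from the constraint bounds sit exactly on the grid, as does the
    observed point — and returns the best strictly feasible grid point.
    Whenever a feasible grid point lies within one step per coordinate of
    the LP optimum (guaranteed for pure minimum-constraint systems, whose
    single-coordinate repair points are grid-aligned), the returned
    objective is within one grid step per coordinate of the LP value.

    With ``grid_step=None`` the step is chosen so each axis carries about
    60 points.  Only problems with at most ``max_free`` free categories are
    accepted, and the total grid is capped at ~3e6 points (raise the step
    if exceeded).
    """
    cats = problem.constraints.categories
    obs = problem.observed.quantities.reindex(cats).fillna(0.0)
    weights, fixed = problem._weights_and_fixed()
    free_idx = [i for i in range(len(cats)) if not fixed[i]]
    if len(free_idx) > max_free:
        raise ValueError(
            f"{len(free_idx)} free categories; the brute-force oracle handles <= {max_free}"
        )

    a_ub, b_ub = problem.constraints.as_upper_bound()

    # box upper bounds: <=-rows with all-nonnegative coefficients cap each
    # coordinate directly; >=-rows (negated in a_ub) cap it through the
    # largest single-coordinate increase that could ever be useful — for a
    # pure minimum-constraint system the optimum provably lies within
    # obs_i + sum_j deficit_j / a_ji of the observed point.
    ubs = []
    deficits = np.maximum(a_ub @ obs.values - b_ub, 0.0)
    for i in free_idx:
        caps = []
        for row, b in zip(a_ub, b_ub):
            if row[i] > 0 and (row >= 0).all():
                caps.append(b / row[i])
        if caps:
            ubs.append(max(min(caps), obs.values[i]))
            continue
        need = sum(
            deficit / -row[i]
            for row, deficit in zip(a_ub, deficits)
            if row[i] < 0 and deficit > 0
        )
        fallback = obs.values[i] + need if need > 0 else obs.values[i] * 10 + 1000.0
        ubs.append(max(fallback, obs.values[i]))

    if grid_step is None:
        grid_step = max(max(ubs) / 60.0, 1e-6)
    n_points = float(np.prod([ub / grid_step + 2 for ub in ubs]))
    if n_points > _ORACLE_MAX_POINTS:
        raise ValueError(
            f"grid of ~{n_points:.2g} points exceeds the oracle cap; "
            f"increase grid_step (box upper bounds {ubs})"
        )

    axes = []
    for i, ub in zip(free_idx, ubs):
        ax = np.arange(0.0, ub + grid_step / 2, grid_step)
        # the observed point and the box edge are always on the grid
        ax = np.unique(np.append(ax, [obs.values[i], ub]))
        axes.append(ax)
    mesh = np.meshgrid(*axes, indexing="ij")
    pts_free = np.stack([m.ravel() for m in mesh], axis=1)

    pts = np.tile(obs.values, (pts_free.shape[0], 1))
    pts[:, free_idx] = pts_free

    feasible = (pts @ a_ub.T <= b_ub + 1e-9 * np.maximum(1.0, np.abs(b_ub))).all(axis=1)
    if not feasible.any():
        diag = problem.constraints.violations(obs).sort_values(ascending=False)
        return LPSolution(
            objective=problem.objective,
            observed=problem.observed,
            status="infeasible",
            diagnostics=diag[diag > 0],
        )
    objective = (np.abs(pts - obs.values) * weights).sum(axis=1)
    objective[~feasible] = np.inf
    best = int(np.argmin(objective))
    optimized = BreakfastPattern(
        pd.Series(pts[best], index=cats),
        population=problem.observed.population,
        provenance=f"oracle-{problem.objective}",
    )
    return LPSolution(
        objective=problem.objective,
        observed=problem.observed,
        status="optimal",
        optimized=optimized,
        distance=float(objective[best]),
    )


def complementarity_gap(solution: LPSolution) -> float:
    """max_i p_i * n_i implied by the optimized pattern (always 0 for the
    deviation split recovered from a single pattern; exposed for tests that
    reconstruct p/n from deltas)."""
    if solution.per_category_change is None:
        raise ValueError("solution carries no per-category changes")
    d = solution.per_category_change["delta_g"].values
    p = np.maximum(d, 0.0)
    n = np.maximum(-d, 0.0)
    return float(np.max(p * n)) if len(d) else 0.0


def enumerate_vertices_2d(
    a_ub: np.ndarray, b_ub: np.ndarray
) -> np.ndarray:  # pragma: no cover - helper for exploratory use
    """Vertices of {x >= 0, A x <= b} for 2-variable systems (intersections
    of active-constraint pairs, filtered for feasibility)."""
    rows = np.vstack([a_ub, -np.eye(2)])
    rhs = np.concatenate([b_ub, np.zeros(2)])
    verts = []
    for i, j in itertools.combinations(range(len(rows)), 2):
        A = np.vstack([rows[i], rows[j]])
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        v = np.linalg.solve(A, np.array([rhs[i], rhs[j]]))
        if (v >= -1e-9).all() and (rows @ v <= rhs + 1e-9).all():
            verts.append(np.maximum(v, 0.0))
    return np.array(verts)
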