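"""End-to-end meal-optimization pipeline.

Chains the stages: breakfast extraction (50 kcal skipper rule) -> NRF9.3
scoring of whole-day intakes -> age-group tertiles -> mean bottom-tertile
breakfast -> both deviation LPs against the breakfast guidelines ->
comparison report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .breakfast import BreakfastPattern, extract_population, mean_pattern
from .composition import CompositionMatrix
from .guidelines import GuidelineSet, default_guidelines
from .nrf import NRFParameters, ScoredPerson, assign_tertiles, score_person
from .optimize import LPSolution, optimize_t1
from .records import IntakeRecord
from .reporting import ComparisonReport, build_report


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one population."""

    population: str
    scored: list[ScoredPerson]
    patterns_by_tertile: dict[str, list[BreakfastPattern]]
    t1_mean: BreakfastPattern
    relative: LPSolution
    absolute: LPSolution
    report: ComparisonReport
    n_skippers: int


def run_pipeline(
    records: list[IntakeRecord],
    composition: CompositionMatrix,
    population: str,
    guidelines: GuidelineSet | None = None,
    nrf_params: NRFParameters | None = None,
) -> PipelineResult:
    """Run the full analysis for one age group.

    Skippers are excluded before scoring; tertiles are assigned within each
    age group from whole-day NRF9.3; the mean T1 breakfast of the requested
    ``population`` is optimized under both objectives.
    """
    guidelines = guidelines if guidelines is not None else default_guidelines(population)
    nrf_params = nrf_params or NRFParameters.default()

    extraction = extract_population(records, composition)
    by_id = {r.person_id: r for r in records}
    consumers = [
        (pid, pattern, by_id[pid])
        for pid, pattern in zip(extraction.consumer_ids, extraction.consumers)
    ]

    scored = [
        score_person(pid, rec.age_group, rec.day_nutrients, nrf_params)
        for pid, _, rec in consumers
    ]
    assign_tertiles(scored)
    tertile_of = {p.person_id: p.tertile for p in scored}

    patterns_by_tertile: dict[str, list[BreakfastPattern]] = {"T1": [], "T2": [], "T3": []}
    for pid, pattern, rec in consumers:
        if rec.age_group == population:
            patterns_by_tertile[tertile_of[pid]].append(pattern)

    if not patterns_by_tertile["T1"]:
        raise ValueError(f"no bottom-tertile breakfast consumers in {population!r}")
    t1_mean = mean_pattern(patterns_by_tertile["T1"], provenance="observed-T1")
    # the LP runs over the full catalog so absent foods stay available to
    # the absolute objective
    t1_mean = BreakfastPattern(
        t1_mean.quantities.reindex(composition.categories).fillna(0.0),
        population=population,
        provenance="observed-T1",
    )

    relative, absolute = optimize_t1(population, composition, t1_mean, guidelines)
    report = build_report(t1_mean, (relative, absolute), composition, guidelines)
    return PipelineResult(
        population=population,
        scored=scored,
        patterns_by_tertile=patterns_by_tertile,
        t1_mean=t1_mean,
        relative=relative,
        absolute=absolute,
        report=report,
        n_skippers=extraction.n_skippers,
    )
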