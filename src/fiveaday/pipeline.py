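"""End-to-end convenience: baseline inputs -> four pathway comparison rows."""

from __future__ import annotations

import pandas as pd

from .accounting import NationalConstants, PathwayReport, build_pathway_report
from .foods import baseline_diet, summarize_diet
from .health import attribution_fv, delta_exposures, health_impact, load_exposure_response
from .optimizer import PATHWAYS, OptimizationResult, build_and_solve_lp

__all__ = ["run_pathway", "run_all_pathways"]


def run_pathway(
    foods: pd.DataFrame,
    pathway_spec,
    pop: pd.DataFrame | None = None,
    er: pd.DataFrame | None = None,
    constants: NationalConstants = NationalConstants(),
    horizon: int = 120,
) -> tuple[PathwayReport, OptimizationResult]:
    """Optimize one pathway and assemble its comparison row.

    Health impacts are computed only when a population table is supplied.
    """
    base = baseline_diet(foods)
    result = build_and_solve_lp(base, foods, pathway_spec)
    summary = summarize_diet(result.diet, foods)
    base_summary = summarize_diet(base, foods)

    delta_le = attribution = None
    if pop is not None and result.status == "optimal":
        er = load_exposure_response() if er is None else er
        deltas = delta_exposures(base, result.diet, foods)
        impact = health_impact(deltas, pop, er, horizon=horizon)
        delta_le = impact.delta_le_months["combined"]
        attribution = attribution_fv(deltas, pop, er, horizon=horizon)

    report = build_pathway_report(
        pathway_spec.id, base_summary, summary, constants,
        delta_le_months=delta_le, attribution_fv=attribution,
        notes=result.binding_notes,
    )
    return report, result


def run_all_pathways(
    foods: pd.DataFrame,
    pop: pd.DataFrame | None = None,
    er: pd.DataFrame | None = None,
    constants: NationalConstants = NationalConstants(),
    horizon: int = 120,
) -> tuple[list[PathwayReport], dict[str, OptimizationResult]]:
    """Baseline row plus all four pathways, in publication order."""
    base_summary = summarize_diet(baseline_diet(foods), foods)
    reports = [build_pathway_report("baseline", base_summary, base_summary, constants)]
    results: dict[str, OptimizationResult] = {}
    for spec in PATHWAYS.values():
        report, result = run_pathway(foods, spec, pop, er, constants, horizon)
        reports.append(report)
        results[spec.id] = result
    return reports, results
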