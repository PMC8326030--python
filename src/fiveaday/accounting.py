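"""Per-capita and national accounting of footprints, cost and health gains.

Per-capita daily deltas (kg CO2eq, L blue water, GBP) are aggregated to
national annual totals for a fixed population over a 365-day year:
megatonnes CO2eq per year for greenhouse gases and cubic kilometres per year
for blue water. Percent changes and national totals are always computed from
unrounded internals; rounding is display-only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import pandas as pd

from .foods import DietSummary, portions

__all__ = [
    "NationalConstants",
    "PathwayReport",
    "national_annual_ghge",
    "national_annual_wf",
    "percent_change",
    "build_pathway_report",
    "render_report",
]


@dataclass(frozen=True)
class NationalConstants:
    """Population scale for national aggregation (UK default, 66.65 M)."""

    population: float = 66_650_000.0
    days_per_year: float = 365.0

    def __post_init__(self):
        if self.population <= 0:
            raise ValueError("population must be > 0")


def national_annual_ghge(delta_kg_per_person_day: float, constants: NationalConstants = NationalConstants()) -> float:
    """Mt CO2eq/year from a per-capita daily delta in kg CO2eq."""
    return delta_kg_per_person_day * constants.population * constants.days_per_year / 1e9


def national_annual_wf(delta_l_per_person_day: float, constants: NationalConstants = NationalConstants()) -> float:
    """km^3 blue water/year from a per-capita daily delta in litres."""
    return delta_l_per_person_day * constants.population * constants.days_per_year / 1e12


def percent_change(baseline_value: float, new_value: float) -> float | None:
    """100 x (new - baseline) / baseline; ``None`` when baseline is zero."""
    if baseline_value == 0:
        return None
    return 100.0 * (new_value - baseline_value) / baseline_value


@dataclass
class PathwayReport:
    """One pathway's row of the cross-pathway comparison table."""

    pathway: str
    energy_kcal: float
    cost_gbp: float
    ghge_kg: float
    blue_wf_l: float
    fv_g: float
    fv_portions: float
    delta_cost_gbp: float
    delta_ghge_kg: float
    delta_wf_l: float
    pct_cost: float | None
    pct_ghge: float | None
    pct_wf: float | None
    national_ghge_mt_per_y: float
    national_wf_km3_per_y: float
    delta_le_months: float | None = None
    attribution_fv_pct: float | None = None
    notes: list[str] = field(default_factory=list)


def build_pathway_report(
    pathway: str,
    baseline: DietSummary,
    summary: DietSummary,
    constants: NationalConstants = NationalConstants(),
    delta_le_months: float | None = None,
    attribution_fv: float | None = None,
    notes: list[str] | None = None,
) -> PathwayReport:
    """Assemble the comparison row for one (possibly baseline) diet."""
    is_baseline = pathway.lower() == "baseline"
    d_cost = summary.cost_gbp - baseline.cost_gbp
    d_ghge = summary.ghge_kg - baseline.ghge_kg
    d_wf = summary.blue_wf_l - baseline.blue_wf_l
    return PathwayReport(
        pathway=pathway,
        energy_kcal=summary.energy_kcal,
        cost_gbp=summary.cost_gbp,
        ghge_kg=summary.ghge_kg,
        blue_wf_l=summary.blue_wf_l,
        fv_g=summary.five_a_day_g,
        fv_portions=portions(summary.five_a_day_g),
        delta_cost_gbp=0.0 if is_baseline else d_cost,
        delta_ghge_kg=0.0 if is_baseline else d_ghge,
        delta_wf_l=0.0 if is_baseline else d_wf,
        pct_cost=None if is_baseline else percent_change(baseline.cost_gbp, summary.cost_gbp),
        pct_ghge=None if is_baseline else percent_change(baseline.ghge_kg, summary.ghge_kg),
        pct_wf=None if is_baseline else percent_change(baseline.blue_wf_l, summary.blue_wf_l),
        national_ghge_mt_per_y=0.0 if is_baseline else national_annual_ghge(d_ghge, constants),
        national_wf_km3_per_y=0.0 if is_baseline else national_annual_wf(d_wf, constants),
        delta_le_months=delta_le_months,
        attribution_fv_pct=None if attribution_fv is None else 100.0 * attribution_fv,
        notes=list(notes or []),
    )


_DISPLAY_ROUNDING = {
    "ghge_kg": 1,
    "blue_wf_l": 1,
    "delta_ghge_kg": 1,
    "delta_wf_l": 1,
    "delta_le_months": 1,
    "cost_gbp": 2,
    "delta_cost_gbp": 2,
    "pct_cost": 0,
    "pct_ghge": 0,
    "pct_wf": 0,
    "attribution_fv_pct": 0,
}


def render_report(reports: list[PathwayReport], fmt: str = "csv") -> str:
    """Render the pathway comparison as CSV or JSON.

    Unrounded values are always emitted; the CSV adds display-rounded
    companion columns (1 decimal for kg/L/months, 2 for GBP, integer
    percents). Percent changes and national totals are computed from
    unrounded internals, which is why a rounded delta of -0.3 kg can sit
    next to a -4.1% change.
    """
    if not reports:
        raise ValueError("render_report: need at least one pathway report")
    rows = [asdict(r) for r in reports]
    if fmt == "json":
        return json.dumps(rows, indent=2)
    if fmt != "csv":
        raise ValueError(f"unknown report format {fmt!r}")
    df = pd.DataFrame(rows).drop(columns=["notes"])
    for col, nd in _DISPLAY_ROUNDING.items():
        disp = df[col].round(nd)
        df[f"{col}_display"] = disp.astype("Int64") if nd == 0 else disp
    return df.to_csv(index=False)
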