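"""Linear-programming pathways from the baseline diet to the 5-a-day target.

Four consumption pathways raise fruit-and-vegetable intake to 400 g/day:

* ``FV_ALL``  -- extra intake from all fruit and vegetable varieties,
  proportionate to current consumption;
* ``VEG_ALL`` -- extra intake from vegetables (incl. legumes) only;
* ``FV_UK``   -- as FV_ALL but restricted to UK-capable varieties;
* ``VEG_UK``  -- as VEG_ALL but restricted to UK-capable varieties.

The construction mirrors the modeled substitution mechanism: eligible fruit
and vegetable groups are scaled by a common factor until the (legume-capped)
5-a-day count reaches the target; the added fruit energy displaces sweet
snacks and the added vegetable energy displaces meat (red, processed and
poultry), each pool shrinking proportionally to its baseline energy share.
Total dietary energy is held at its baseline value, and any residual energy
imbalance (an exhausted substitution pool) is rebalanced through the
remaining "free" foods by a linear program minimizing the total relative
deviation from the baseline diet.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .foods import LEGUME_CAP_G, align_diet, count_five_a_day

__all__ = [
    "PathwaySpec",
    "OptimizationResult",
    "InfeasiblePathwayError",
    "PATHWAYS",
    "pathway",
    "eligible_set",
    "solve_scale_factor",
    "scaled_diet",
    "substitution_requirements",
    "build_and_solve_lp",
]

FV_CATEGORIES = frozenset({"fruit", "vegetable", "legume"})
VEG_CATEGORIES = frozenset({"vegetable", "legume"})
MEAT_CATEGORIES = ("red_meat", "processed_meat", "poultry")

#: Foods "directly modified" by a pathway (all fruit and vegetables, sweet
#: snacks and meat); everything else is free to move in the deviation LP.
DIRECT_CATEGORIES = frozenset(
    {"fruit", "vegetable", "legume", "sweet_snack", *MEAT_CATEGORIES}
)

_TOL = 1e-9


class InfeasiblePathwayError(ValueError):
    """Raised when a pathway target cannot be met from the eligible foods."""


@dataclass(frozen=True)
class PathwaySpec:
    """One consumption pathway to the 5-a-day target."""

    id: str
    increase_categories: frozenset
    uk_only: bool
    target_g: float = 400.0
    legume_cap_g: float = LEGUME_CAP_G


PATHWAYS: dict[str, PathwaySpec] = {
    "FV_ALL": PathwaySpec("FV_ALL", FV_CATEGORIES, uk_only=False),
    "VEG_ALL": PathwaySpec("VEG_ALL", VEG_CATEGORIES, uk_only=False),
    "FV_UK": PathwaySpec("FV_UK", FV_CATEGORIES, uk_only=True),
    "VEG_UK": PathwaySpec("VEG_UK", VEG_CATEGORIES, uk_only=True),
}


def pathway(name: str) -> PathwaySpec:
    """Look up a pathway by id, accepting ``fv-all`` / ``FV_ALL`` spellings."""
    key = name.replace("-", "_").upper()
    try:
        return PATHWAYS[key]
    except KeyError:
        raise KeyError(f"unknown pathway {name!r}; expected one of {sorted(PATHWAYS)}")


@dataclass
class OptimizationResult:
    """An optimized pathway diet and the bookkeeping behind it."""

    pathway_id: str
    diet: pd.Series
    scale_factor: float
    delta_e_fruit_kcal: float
    delta_e_veg_kcal: float
    objective: float
    status: str  # "optimal" | "infeasible"
    binding_notes: list[str] = field(default_factory=list)

    def run_log(self) -> dict:
        """Machine-readable record of the solve (for JSON serialization)."""
        return {
            "pathway": self.pathway_id,
            "scale_factor": self.scale_factor,
            "delta_e_fruit_kcal": self.delta_e_fruit_kcal,
            "delta_e_veg_kcal": self.delta_e_veg_kcal,
            "objective": self.objective,
            "status": self.status,
            "binding_notes": list(self.binding_notes),
        }


def eligible_set(foods: pd.DataFrame, spec: PathwaySpec) -> pd.Index:
    """Food ids whose intake a pathway is allowed to scale up.

    Counting foods in the pathway's increase categories, restricted to
    UK-capable varieties for the *_UK pathways; zero-baseline foods are
    excluded (their relative scaling is undefined and they stay at zero).
    """
    mask = (
        foods["counts_5aday"]
        & foods["category"].isin(spec.increase_categories)
        & (foods["baseline_intake_g"] > 0)
    )
    if spec.uk_only:
        mask &= foods["uk_capable"]
    ids = pd.Index(foods.loc[mask, "id"])
    if len(ids) == 0:
        raise InfeasiblePathwayError(
            f"pathway {spec.id}: no eligible foods "
            f"(categories {sorted(spec.increase_categories)}, uk_only={spec.uk_only})"
        )
    return ids


def solve_scale_factor(diet, foods: pd.DataFrame, spec: PathwaySpec) -> float:
    """Common factor by which eligible foods are scaled to hit the target.

    The 5-a-day count is piecewise linear in the factor ``s`` because of the
    legume cap; each piece is solved in closed form. Returns 1.0 when the
    baseline already meets the target.
    """
    diet = align_diet(diet, foods)
    cap = spec.legume_cap_g
    if count_five_a_day(diet, foods, cap) >= spec.target_g - _TOL:
        return 1.0

    elig = set(eligible_set(foods, spec))
    counted = foods["counts_5aday"].values
    cat = foods["category"].values
    is_elig = np.array([i in elig for i in foods["id"]])
    x = diet.values

    fv = counted & ((cat == "fruit") | (cat == "vegetable"))
    lg = counted & (cat == "legume")
    fv_e = float(x[fv & is_elig].sum())
    fv_fix = float(x[fv & ~is_elig].sum())
    lg_e = float(x[lg & is_elig].sum())
    lg_fix = float(x[lg & ~is_elig].sum())

    if fv_e + lg_e <= 0:
        raise InfeasiblePathwayError(f"pathway {spec.id}: eligible baseline mass is zero")

    # piece 1: total legumes below the cap, count linear in s
    if fv_e + lg_e > 0:
        s = (spec.target_g - fv_fix - lg_fix) / (fv_e + lg_e)
        if lg_fix + s * lg_e <= cap + _TOL and s >= 1.0 - _TOL:
            return max(s, 1.0)
    # piece 2: legume contribution pinned at the cap
    if fv_e <= 0:
        shortfall = spec.target_g - (fv_fix + cap)
        raise InfeasiblePathwayError(
            f"pathway {spec.id}: legume cap makes the count bounded below the "
            f"target (shortfall {shortfall:.3f} g with no eligible non-legume mass)"
        )
    s = (spec.target_g - fv_fix - cap) / fv_e
    if s < 1.0 - _TOL:
        raise InfeasiblePathwayError(
            f"pathway {spec.id}: inconsistent scale factor {s:.6f} < 1"
        )
    return max(s, 1.0)


def scaled_diet(diet, foods: pd.DataFrame, spec: PathwaySpec, s: float) -> pd.Series:
    """Apply the scale factor to eligible foods, leaving all others unchanged."""
    diet = align_diet(diet, foods)
    out = diet.copy()
    out.loc[eligible_set(foods, spec)] *= s
    return out


def substitution_requirements(
    baseline, scaled, foods: pd.DataFrame
) -> tuple[float, float]:
    """Energy added by the fruit and the vegetable scaling, kcal/day.

    The fruit increment displaces sweet snacks and the vegetable+legume
    increment displaces meat, on a per-kilocalorie basis.
    """
    baseline = align_diet(baseline, foods)
    scaled = align_diet(scaled, foods)
    e = foods["energy_density_kcal_per_g"].values
    cat = foods["category"].values
    delta = scaled.values - baseline.values
    de_fruit = float((delta * e)[cat == "fruit"].sum())
    de_veg = float((delta * e)[(cat == "vegetable") | (cat == "legume")].sum())
    return de_fruit, de_veg


def _shrink_pool(
    x: np.ndarray, e: np.ndarray, pool_mask: np.ndarray, delta_e: float, label: str
) -> tuple[np.ndarray, float, list[str]]:
    """Shrink a substitution pool by ``delta_e`` kcal, proportionally.

    Every pool food is scaled by the same factor, which removes energy in
    proportion to each food's baseline energy contribution. If the pool holds
    less energy than required it is exhausted (all pool foods go to zero) and
    the residual energy is returned for the free-food rebalance.
    """
    notes: list[str] = []
    pool_energy = float((x * e)[pool_mask].sum())
    out = x.copy()
    if delta_e <= _TOL:
        return out, 0.0, notes
    if pool_energy >= delta_e:
        factor = 1.0 - delta_e / pool_energy
        out[pool_mask] *= factor
        if factor <= _TOL:
            notes.append(f"{label} pool fully consumed")
        return out, 0.0, notes
    out[pool_mask] = 0.0
    residual = delta_e - pool_energy
    notes.append(
        f"{label} pool exhausted ({pool_energy:.3f} kcal available, "
        f"{residual:.3f} kcal rebalanced through free foods)"
    )
    return out, residual, notes


def build_and_solve_lp(
    baseline, foods: pd.DataFrame, spec: PathwaySpec
) -> OptimizationResult:
    """Solve one pathway end to end.

    Steps: (a) scale eligible fruit/vegetable groups to the 400-g count;
    (b) displace sweet-snack energy by the fruit increment and meat energy by
    the vegetable increment, proportionally within each pool with per-food
    floors at zero; (c) hold total dietary energy at baseline, rebalancing
    any exhausted-pool residual through the free foods ("other" category) by
    minimizing the total relative deviation sum(|x-b|/b), linearized with
    split nonnegative deviation variables and solved with HiGHS.
    """
    baseline = align_diet(baseline, foods)
    s = solve_scale_factor(baseline, foods, spec)
    scaled = scaled_diet(baseline, foods, spec, s)
    de_fruit, de_veg = substitution_requirements(baseline, scaled, foods)

    e = foods["energy_density_kcal_per_g"].values
    cat = foods["category"].values
    x = scaled.values.copy()
    notes: list[str] = []

    sweet = cat == "sweet_snack"
    meat = np.isin(cat, MEAT_CATEGORIES)
    x, resid_sweet, n1 = _shrink_pool(x, e, sweet, de_fruit, "sweet_snack")
    x, resid_meat, n2 = _shrink_pool(x, e, meat, de_veg, "meat")
    notes += n1 + n2
    residual = resid_sweet + resid_meat  # surplus kcal to remove from free foods

    free = (cat == "other") & (baseline.values > 0)
    objective = 0.0
    status = "optimal"
    if residual > _TOL:
        b = baseline.values[free]
        ef = e[free]
        n = len(b)
        free_energy = float((b * ef).sum())
        if n == 0 or free_energy < residual - _TOL:
            status = "infeasible"
            notes.append(
                "free-food energy balance violated: residual "
                f"{residual:.3f} kcal exceeds free-food energy {free_energy:.3f} kcal"
            )
        else:
            # variables [d_plus, d_minus]; x_free = b + d_plus - d_minus
            c = np.concatenate([1.0 / b, 1.0 / b])
            a_eq = np.concatenate([ef, -ef])[None, :]
            b_eq = np.array([-residual])
            bounds = [(0.0, None)] * n + [(0.0, bi) for bi in b]
            res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
            if not res.success:
                status = "infeasible"
                notes.append(f"free-food energy balance LP failed: {res.message}")
            else:
                d_plus, d_minus = res.x[:n], res.x[n:]
                x[free] = b + d_plus - d_minus
                objective = float(res.fun)

    diet = pd.Series(np.maximum(x, 0.0), index=baseline.index, name="intake_g")
    return OptimizationResult(
        pathway_id=spec.id,
        diet=diet,
        scale_factor=s,
        delta_e_fruit_kcal=de_fruit,
        delta_e_veg_kcal=de_veg,
        objective=objective,
        status=status,
        binding_notes=notes,
    )
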