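"""Food-group data model: diets, trade-weighted footprints, 5-a-day counting.

Everything downstream (pathway optimization, health impact assessment,
footprint/cost accounting) consumes the two tabular inputs defined here:

* a **food-group table** -- one row per compositionally distinct food group,
  carrying its baseline national-average intake (g/person/day), energy
  density (kcal/g), retail price (GBP/kg) and supply-weighted environmental
  footprint factors (kg CO2eq/kg and L blue water/kg);
* an optional **trade-share table** decomposing each food's footprint factors
  by origin country, so the food-level factors are supply-weighted means over
  current import/domestic-production patterns.

Internal units are g/person/day, kcal, GBP, kg CO2eq and litres throughout;
per-kilogram factors are divided by 1000 at the point of use.

The "5-a-day" counting rules live here as well: fruit juice and potatoes
never count toward the 400-g target (they keep their footprints and cost in
diet totals), and legumes count for at most one 80-g portion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "FOOD_COLUMNS",
    "TRADE_COLUMNS",
    "ValidationError",
    "DietSummary",
    "validate_foods",
    "read_foods_csv",
    "write_foods_csv",
    "validate_trade",
    "read_trade_csv",
    "write_trade_csv",
    "weighted_footprint",
    "apply_trade_weights",
    "baseline_diet",
    "align_diet",
    "summarize_diet",
    "count_five_a_day",
    "portions",
]

#: Food categories. ``legume`` is split out of ``vegetable`` because legumes
#: have their own 5-a-day cap and their own exposure-response relations; the
#: "vegetables" of the dietary survey are ``vegetable`` + ``legume`` here.
CATEGORIES = (
    "fruit",
    "vegetable",
    "legume",
    "red_meat",
    "processed_meat",
    "poultry",
    "sweet_snack",
    "other",
)

FOOD_COLUMNS = [
    "id",
    "name",
    "category",
    "counts_5aday",
    "uk_capable",
    "baseline_intake_g",
    "energy_density_kcal_per_g",
    "price_gbp_per_kg",
    "ghge_kgco2e_per_kg",
    "bluewf_l_per_kg",
]

TRADE_COLUMNS = ["food_id", "origin", "share", "ghge_kgco2e_per_kg", "bluewf_l_per_kg"]

_NUMERIC_FOOD_COLUMNS = FOOD_COLUMNS[5:]

#: Mass of one 5-a-day portion, grams.
PORTION_G = 80.0

#: Default cap on the legume contribution to the 5-a-day count (one portion).
LEGUME_CAP_G = 80.0


class ValidationError(ValueError):
    """Raised when an input table violates the schema or an invariant."""


@dataclass(frozen=True)
class DietSummary:
    """Whole-diet aggregates for one national-average diet.

    ``fruit_g``, ``veg_nonlegume_g`` and ``legume_g`` are restricted to foods
    that count toward 5-a-day (fruit juice and potatoes excluded), so that
    ``five_a_day_g = fruit_g + veg_nonlegume_g + min(legume_g, cap)``.
    """

    energy_kcal: float
    cost_gbp: float
    ghge_kg: float
    blue_wf_l: float
    fruit_g: float
    veg_nonlegume_g: float
    legume_g: float
    five_a_day_g: float


def _as_bool(series: pd.Series, col: str) -> pd.Series:
    mapping = {
        True: True, False: False, "true": True, "false": False,
        "True": True, "False": False, 1: True, 0: False, "1": True, "0": False,
    }
    out = series.map(mapping)
    if out.isna().any():
        row = int(series.index[out.isna()][0])
        raise ValidationError(
            f"foods row {row + 2}: column {col!r} must be boolean, got {series[row]!r}"
        )
    return out.astype(bool)


def validate_foods(foods: pd.DataFrame) -> pd.DataFrame:
    """Validate a food-group table and return a typed copy.

    Row numbers in error messages are 1-based CSV line numbers (header is
    line 1), so they point at the offending line of ``foods.csv``.
    """
    missing = [c for c in FOOD_COLUMNS if c not in foods.columns]
    if missing:
        raise ValidationError(f"foods table missing columns: {missing}")
    out = foods.loc[:, FOOD_COLUMNS].copy().reset_index(drop=True)

    out["id"] = out["id"].astype(str)
    dup = out["id"][out["id"].duplicated()]
    if len(dup):
        raise ValidationError(f"foods table has duplicate ids: {sorted(set(dup))}")

    bad = ~out["category"].isin(CATEGORIES)
    if bad.any():
        row = int(out.index[bad][0])
        raise ValidationError(
            f"foods row {row + 2} (id={out.at[row, 'id']}): unknown category "
            f"{out.at[row, 'category']!r}; expected one of {CATEGORIES}"
        )

    for col in ("counts_5aday", "uk_capable"):
        out[col] = _as_bool(out[col], col)

    for col in _NUMERIC_FOOD_COLUMNS:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            row = int(out.index[bad][0])
            raise ValidationError(
                f"foods row {row + 2} (id={out.at[row, 'id']}): column {col!r} "
                f"must be a finite number >= 0, got {out.at[row, col]!r}"
            )
        out[col] = vals.astype(float)

    # only fruit/vegetable/legume groups may count toward the target
    countable = out["category"].isin(("fruit", "vegetable", "legume"))
    bad = out["counts_5aday"] & ~countable
    if bad.any():
        row = int(out.index[bad][0])
        raise ValidationError(
            f"foods row {row + 2} (id={out.at[row, 'id']}): counts_5aday=True "
            f"is only valid for fruit/vegetable/legume categories"
        )
    return out


def read_foods_csv(path) -> pd.DataFrame:
    """Read and validate ``foods.csv`` (UTF-8, '.' decimal, header required)."""
    return validate_foods(pd.read_csv(path, comment="#"))


def write_foods_csv(foods: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        foods.to_csv(fh, index=False)


def validate_trade(trade: pd.DataFrame, foods: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a trade-share table; shares must sum to 1 per food."""
    missing = [c for c in TRADE_COLUMNS if c not in trade.columns]
    if missing:
        raise ValidationError(f"trade table missing columns: {missing}")
    out = trade.loc[:, TRADE_COLUMNS].copy().reset_index(drop=True)
    out["food_id"] = out["food_id"].astype(str)
    out["origin"] = out["origin"].astype(str)
    for col in ("share", "ghge_kgco2e_per_kg", "bluewf_l_per_kg"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            row = int(out.index[bad][0])
            raise ValidationError(
                f"trade row {row + 2} (food_id={out.at[row, 'food_id']}): column "
                f"{col!r} must be a finite number >= 0"
            )
        out[col] = vals.astype(float)
    if (out["share"] > 1 + 1e-9).any():
        raise ValidationError("trade shares must lie in [0, 1]")
    sums = out.groupby("food_id")["share"].sum()
    off = sums[(sums - 1.0).abs() > 1e-9]
    if len(off):
        fid = off.index[0]
        raise ValidationError(
            f"trade shares for food {fid!r} sum to {off.iloc[0]:.12g}, expected 1"
        )
    if foods is not None:
        unknown = set(out["food_id"]) - set(foods["id"])
        if unknown:
            raise ValidationError(f"trade table references unknown foods: {sorted(unknown)}")
    return out


def read_trade_csv(path, foods: pd.DataFrame | None = None) -> pd.DataFrame:
    return validate_trade(pd.read_csv(path, comment="#"), foods)


def write_trade_csv(trade: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        trade.to_csv(fh, index=False)


def weighted_footprint(shares: pd.DataFrame) -> tuple[float, float]:
    """Supply-weighted footprint factors for one food.

    ``shares`` holds the origin rows of a single food (columns ``share``,
    ``ghge_kgco2e_per_kg``, ``bluewf_l_per_kg``). Returns the share-weighted
    (ghge, blue_wf) per kg; by convexity each lies within the min/max of the
    contributing origin factors.
    """
    if len(shares) == 0:
        raise ValidationError("weighted_footprint: empty share table")
    total = float(shares["share"].sum())
    if abs(total - 1.0) > 1e-9:
        food = shares["food_id"].iloc[0] if "food_id" in shares else "<unknown>"
        raise ValidationError(
            f"shares for food {food!r} sum to {total:.12g}, expected 1"
        )
    ghge = float(np.dot(shares["share"], shares["ghge_kgco2e_per_kg"]))
    wf = float(np.dot(shares["share"], shares["bluewf_l_per_kg"]))
    return ghge, wf


def apply_trade_weights(foods: pd.DataFrame, trade: pd.DataFrame) -> pd.DataFrame:
    """Replace food-level footprint factors by supply-weighted origin means.

    Foods absent from the trade table keep their direct (single-origin)
    factors.
    """
    trade = validate_trade(trade, foods)
    out = foods.copy()
    for fid, grp in trade.groupby("food_id"):
        ghge, wf = weighted_footprint(grp)
        mask = out["id"] == fid
        out.loc[mask, "ghge_kgco2e_per_kg"] = ghge
        out.loc[mask, "bluewf_l_per_kg"] = wf
    return out


def baseline_diet(foods: pd.DataFrame) -> pd.Series:
    """The baseline national-average diet vector (g/person/day), by food id."""
    return pd.Series(foods["baseline_intake_g"].values, index=foods["id"].values, name="intake_g")


def align_diet(diet: Mapping[str, float] | pd.Series, foods: pd.DataFrame) -> pd.Series:
    """Check a diet vector against the food table and return it food-ordered.

    Every food id must be present exactly once, with no extra ids and no
    negative or non-finite entries.
    """
    s = pd.Series(diet, dtype=float)
    ids = pd.Index(foods["id"])
    extra = s.index.difference(ids)
    if len(extra):
        raise ValidationError(f"diet contains unknown food ids: {list(extra[:5])}")
    missing = ids.difference(s.index)
    if len(missing):
        raise ValidationError(f"diet is missing food ids: {list(missing[:5])}")
    s = s.reindex(ids)
    if (~np.isfinite(s.values)).any() or (s.values < 0).any():
        bad = s.index[~np.isfinite(s.values) | (s.values < 0)][0]
        raise ValidationError(f"diet intake for {bad!r} must be a finite number >= 0")
    return s


def count_five_a_day(
    diet, foods: pd.DataFrame, legume_cap_g: float = LEGUME_CAP_G
) -> float:
    """Grams per day counting toward 5-a-day.

    Counted fruit plus counted non-legume vegetables, plus legumes capped at
    one portion (``legume_cap_g``). Fruit juice and potatoes carry
    ``counts_5aday=False`` and are excluded.
    """
    diet = align_diet(diet, foods)
    counted = foods["counts_5aday"].values
    cat = foods["category"].values
    x = diet.values
    fruit = float(x[counted & (cat == "fruit")].sum())
    veg = float(x[counted & (cat == "vegetable")].sum())
    legume = float(x[counted & (cat == "legume")].sum())
    return fruit + veg + min(legume, legume_cap_g)


def summarize_diet(
    diet, foods: pd.DataFrame, legume_cap_g: float = LEGUME_CAP_G
) -> DietSummary:
    """Energy, cost, footprint and 5-a-day aggregates of one diet."""
    diet = align_diet(diet, foods)
    x = diet.values
    energy = float(np.dot(x, foods["energy_density_kcal_per_g"].values))
    kg = x / 1000.0
    cost = float(np.dot(kg, foods["price_gbp_per_kg"].values))
    ghge = float(np.dot(kg, foods["ghge_kgco2e_per_kg"].values))
    wf = float(np.dot(kg, foods["bluewf_l_per_kg"].values))
    counted = foods["counts_5aday"].values
    cat = foods["category"].values
    fruit = float(x[counted & (cat == "fruit")].sum())
    veg = float(x[counted & (cat == "vegetable")].sum())
    legume = float(x[counted & (cat == "legume")].sum())
    return DietSummary(
        energy_kcal=energy,
        cost_gbp=cost,
        ghge_kg=ghge,
        blue_wf_l=wf,
        fruit_g=fruit,
        veg_nonlegume_g=veg,
        legume_g=legume,
        five_a_day_g=fruit + veg + min(legume, legume_cap_g),
    )


def portions(grams: float, portion_g: float = PORTION_G) -> float:
    """Convert grams to 80-g 5-a-day portions (400 g -> 5.0)."""
    if grams < 0:
        raise ValidationError("portions: grams must be >= 0")
    return grams / portion_g
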