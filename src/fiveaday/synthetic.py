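"""Seedable synthetic inputs with the structure of the UK dietary survey data.

The real inputs of the analysis (individual-level NDNS food diaries, the
supplementary per-food energy/price/footprint tables, ONS population counts
and GBD cause-specific mortality) are not redistributable. This module
generates synthetic stand-ins that preserve the published *structure*:

* 265 compositionally distinct food groups (48 fruit, 64 vegetable, 153
  other), with heavy-tailed (log-normal) intakes -- a few foods dominate
  each category;
* the calibrated fixture pins the named top fruits and vegetables at their
  published national-average intakes (bananas 23.84 g/d, tomatoes 24.93 g/d,
  baked beans 15.47 g/d, ...) and rescales every drawn quantity
  multiplicatively so the whole-diet aggregates hit the published baseline
  exactly: 88 g fruit, 140 g vegetables, 1744 kcal, GBP 6.78, 6.2 kg CO2eq
  and 611.4 L blue water per person per day;
* a fruit-juice and a potato group that never count toward 5-a-day;
* a trade-share table with UK origins drawing systematically lower blue-water
  factors than foreign origins (UK production relies more on rainfall);
* an age/sex population with Gompertz-Makeham all-cause mortality
  (life expectancy at birth in the high-70s to low-80s) and smooth
  age-dependent cause-specific fractions for the six modeled outcomes.

Per-food energy densities, prices and footprint factors are documented
assumptions drawn from realistic category ranges, not reproductions of the
unpublished per-food values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .foods import validate_foods, validate_trade, write_foods_csv, write_trade_csv
from .health import OUTCOMES, load_exposure_response, validate_population

__all__ = ["GeneratorConfig", "generate_food_table", "generate_trade_shares",
           "generate_population", "generate_inputs"]

# Published national-average intakes of the top fruits and vegetables
# (g/person/day); together they provide ~90% of each category.
PINNED_FRUIT = {
    "Bananas": 23.84, "Apples": 18.27, "Pears": 5.64, "Oranges": 5.32,
    "Tangerines": 5.32, "Grapes": 5.12, "Strawberries": 4.72,
    "Canned fruit": 1.91, "Melons": 1.83, "Pineapple": 1.61,
    "Blueberries": 1.44, "Mangoes": 1.43, "Nectarines": 1.29, "Plums": 1.20,
}
PINNED_VEG = {
    "Tomatoes": 24.93, "Baked beans": 15.47, "Onions": 13.88, "Carrots": 13.57,
    "Peas": 8.18, "Broccoli": 6.57, "Peppers": 5.85, "Cucumber": 4.83,
    "Mushrooms": 4.56, "Lettuce": 4.14, "Cabbage": 3.72, "Cauliflower": 2.93,
    "Green beans": 2.74, "Other beans": 2.47, "Sweet corn": 2.46,
    "Sweet potato": 1.63, "Lentils": 1.55, "Spinach": 1.51, "Parsnips": 1.50,
    "Mixed-leaf salad": 1.44, "Leeks": 1.42,
}
#: Pulses within the vegetable category; capped at one 5-a-day portion.
LEGUME_NAMES = {"Baked beans", "Other beans", "Lentils"}
#: Varieties that could plausibly be grown to a greater extent in the UK.
UK_CAPABLE_PINNED = {
    "Apples", "Pears", "Strawberries", "Blueberries", "Plums",
    "Tomatoes", "Onions", "Carrots", "Peas", "Broccoli", "Cucumber",
    "Mushrooms", "Lettuce", "Cabbage", "Cauliflower", "Green beans",
    "Other beans", "Spinach", "Parsnips", "Mixed-leaf salad", "Leeks",
}

_FOREIGN_ORIGINS = ["ES", "NL", "IT", "FR", "ZA", "BR", "CR", "MA", "EG", "IN", "KE", "PE"]

# category -> (energy-density range kcal/g, mean price GBP/kg,
#              mean GHGE kg CO2eq/kg, mean blue WF L/kg)
_CATEGORY_PARAMS = {
    "fruit": ((0.3, 0.9), 2.8, 1.1, 65.0),
    "vegetable": ((0.2, 0.8), 2.2, 0.9, 45.0),
    "legume": ((0.7, 1.1), 1.8, 0.9, 50.0),
    "sweet_snack": ((3.5, 5.5), 8.0, 3.0, 100.0),
    "red_meat": ((1.5, 3.5), 8.0, 20.0, 100.0),
    "processed_meat": ((1.5, 3.5), 7.0, 12.0, 90.0),
    "poultry": ((1.5, 2.5), 5.0, 6.0, 60.0),
    "other": ((0.5, 3.5), 4.0, 2.2, 50.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-input generator.

    The defaults are the study conditions: published group counts and
    baseline whole-diet aggregates. ``calibration="paper"`` pins the named
    top fruits and vegetables at their published intakes; ``"random"`` draws
    every intake (aggregates are still rescaled to the targets).
    """

    seed: int = 0
    calibration: str = "paper"
    n_fruit: int = 48
    n_veg: int = 64
    n_other: int = 153
    fruit_g: float = 88.0
    veg_g: float = 140.0
    energy_kcal: float = 1744.0
    cost_gbp: float = 6.78
    ghge_kg: float = 6.2
    wf_l: float = 611.4
    uk_capable_fraction: dict = field(
        default_factory=lambda: {"fruit": 0.35, "vegetable": 0.8, "legume": 0.6}
    )
    max_foreign_origins: int = 3
    total_population: float = 66_650_000.0

    def __post_init__(self):
        if min(self.n_fruit, self.n_veg, self.n_other) <= 0:
            raise ValueError("group counts must be positive")
        targets = (self.fruit_g, self.veg_g, self.energy_kcal, self.cost_gbp,
                   self.ghge_kg, self.wf_l)
        if min(targets) <= 0:
            raise ValueError("baseline aggregate targets must be positive")
        if self.calibration not in ("paper", "random"):
            raise ValueError("calibration must be 'paper' or 'random'")
        if self.calibration == "paper" and (
            self.n_fruit < len(PINNED_FRUIT) + 2 or self.n_veg < len(PINNED_VEG) + 2
        ):
            raise ValueError("paper calibration needs the default group counts")


def _lognormal_shares(rng, n, sigma=1.0):
    draws = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    return draws / draws.sum()


def generate_food_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the 265-group food table, calibrated to the baseline aggregates.

    Counted fruit sums to ``fruit_g`` and counted vegetables (including
    legumes) to ``veg_g`` exactly; prices, GHGE and blue-WF factors and the
    non-fruit/vegetable intakes are rescaled multiplicatively so whole-diet
    cost, energy and footprints hit their targets exactly. Same seed and
    config give a bit-identical table.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []

    def add(name, category, counts, uk, intake):
        rows.append({
            "id": f"G{len(rows) + 1:03d}", "name": name, "category": category,
            "counts_5aday": counts, "uk_capable": uk, "baseline_intake_g": intake,
        })

    paper = config.calibration == "paper"
    uk_frac = config.uk_capable_fraction

    # --- fruit: pinned top varieties + a log-normal tail + one juice group
    n_tail_fruit = config.n_fruit - 1 - (len(PINNED_FRUIT) if paper else 0)
    if paper:
        for name, g in PINNED_FRUIT.items():
            add(name, "fruit", True, name in UK_CAPABLE_PINNED, g)
        tail_total = config.fruit_g - sum(PINNED_FRUIT.values())
    else:
        tail_total = config.fruit_g
    tail = _lognormal_shares(rng, n_tail_fruit) * tail_total
    for k, g in enumerate(tail):
        add(f"Fruit {k + 1}", "fruit", True,
            bool(rng.random() < uk_frac["fruit"]), float(g))
    add("Fruit juice", "fruit", False, False, float(rng.uniform(50, 90)))

    # --- vegetables: pinned varieties (three of them legumes) + tail + potato
    n_tail_veg = config.n_veg - 1 - (len(PINNED_VEG) if paper else 3)
    if paper:
        for name, g in PINNED_VEG.items():
            cat = "legume" if name in LEGUME_NAMES else "vegetable"
            add(name, cat, True, name in UK_CAPABLE_PINNED, g)
        tail_total = config.veg_g - sum(PINNED_VEG.values())
    else:
        legume_total = 0.14 * config.veg_g
        for k, g in enumerate(_lognormal_shares(rng, 3) * legume_total):
            add(f"Legume {k + 1}", "legume", True,
                bool(rng.random() < uk_frac["legume"]), float(g))
        tail_total = config.veg_g - legume_total
    tail = _lognormal_shares(rng, n_tail_veg) * tail_total
    for k, g in enumerate(tail):
        add(f"Vegetable {k + 1}", "vegetable", True,
            bool(rng.random() < uk_frac["vegetable"]), float(g))
    add("Potatoes", "vegetable", False, True, float(rng.uniform(60, 100)))

    # --- remaining groups: substitution pools plus everything else
    pools = [("Sweet snack", "sweet_snack", 12, 70.0), ("Red meat", "red_meat", 8, 30.0),
             ("Processed meat", "processed_meat", 8, 28.0), ("Poultry", "poultry", 4, 35.0)]
    n_free = config.n_other - sum(n for _, _, n, _ in pools)
    for label, cat, n, total_g in pools:
        for k, g in enumerate(_lognormal_shares(rng, n, sigma=0.6) * total_g):
            add(f"{label} {k + 1}", cat, False, False, float(g))
    for k, g in enumerate(_lognormal_shares(rng, n_free) * 900.0):
        add(f"Other food {k + 1}", "other", False, False, float(g))

    foods = pd.DataFrame(rows)

    # per-food properties from category ranges; UK-capable fruit & veg run
    # slightly cheaper in energy and dearer in price (as reported for
    # UK-capable varieties), and much lower in blue water
    e_lo_hi = np.array([_CATEGORY_PARAMS[c][0] for c in foods["category"]])
    energy = rng.uniform(e_lo_hi[:, 0], e_lo_hi[:, 1])
    price = np.array([_CATEGORY_PARAMS[c][1] for c in foods["category"]]) * rng.lognormal(
        0.0, 0.4, len(foods))
    ghge = np.array([_CATEGORY_PARAMS[c][2] for c in foods["category"]]) * rng.lognormal(
        0.0, 0.3, len(foods))
    wf = np.array([_CATEGORY_PARAMS[c][3] for c in foods["category"]]) * rng.lognormal(
        0.0, 0.5, len(foods))
    fv = foods["category"].isin(("fruit", "vegetable", "legume")).values
    uk_fv = fv & foods["uk_capable"].values
    energy = np.where(uk_fv, energy * 0.85, energy)
    price = np.where(uk_fv, price * 1.3, price)
    wf = np.where(uk_fv, wf * 0.4, wf)

    foods["energy_density_kcal_per_g"] = energy
    foods["price_gbp_per_kg"] = price
    foods["ghge_kgco2e_per_kg"] = ghge
    foods["bluewf_l_per_kg"] = wf

    # calibration: rescale non-F&V intakes to the energy target, then the
    # per-kg factors to the cost/GHGE/WF targets (all multiplicative)
    intake = foods["baseline_intake_g"].values.copy()
    e_fv = float((intake * energy)[fv].sum())  # incl. fruit juice and potatoes
    scalable = ~fv
    e_scalable = float((intake * energy)[scalable].sum())
    need = config.energy_kcal - e_fv
    if need <= 0 or e_scalable <= 0:
        raise ValueError("energy target unreachable with nonnegative intakes")
    intake[scalable] *= need / e_scalable
    foods["baseline_intake_g"] = intake

    kg = intake / 1000.0
    foods["price_gbp_per_kg"] *= config.cost_gbp / float(np.dot(kg, price))
    foods["ghge_kgco2e_per_kg"] *= config.ghge_kg / float(np.dot(kg, ghge))
    foods["bluewf_l_per_kg"] *= config.wf_l / float(np.dot(kg, wf))
    return validate_foods(foods)


def generate_trade_shares(config: GeneratorConfig, foods: pd.DataFrame) -> pd.DataFrame:
    """Origin shares and origin-specific footprint factors for fruit & veg.

    Per food: a Dirichlet split over UK plus 1-3 foreign origins (about one
    food in ten is single-origin, and one in ten uses a GLOBAL fallback row
    instead of named countries). Origin factors are drawn so their
    share-weighted mean equals the food's supply-weighted factor exactly,
    with UK blue-water factors systematically below foreign ones.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    fv = foods[foods["category"].isin(("fruit", "vegetable", "legume"))]
    for _, food in fv.iterrows():
        if rng.random() < 0.1:
            origins = ["UK" if rng.random() < 0.5 else "GLOBAL"]
            shares = np.array([1.0])
        else:
            n_foreign = int(rng.integers(1, config.max_foreign_origins + 1))
            foreign = list(rng.choice(_FOREIGN_ORIGINS, size=n_foreign, replace=False))
            if rng.random() < 0.1:
                foreign[-1] = "GLOBAL"
            origins = ["UK"] + foreign
            shares = rng.dirichlet(np.ones(len(origins)))
        ghge_mult = rng.lognormal(0.0, 0.25, len(origins))
        wf_mult = rng.lognormal(0.0, 0.3, len(origins))
        wf_mult[0] *= 0.45 if origins[0] == "UK" else 1.0
        wf_mult[1:] *= 1.4
        ghge_mult /= float(np.dot(shares, ghge_mult))
        wf_mult /= float(np.dot(shares, wf_mult))
        for origin, share, gm, wm in zip(origins, shares, ghge_mult, wf_mult):
            rows.append({
                "food_id": food["id"], "origin": origin, "share": float(share),
                "ghge_kgco2e_per_kg": float(food["ghge_kgco2e_per_kg"] * gm),
                "bluewf_l_per_kg": float(food["bluewf_l_per_kg"] * wm),
            })
    return validate_trade(pd.DataFrame(rows), foods)


# Gompertz-Makeham all-cause mortality m(a) = A + B * exp(g * a), by sex;
# tuned to put synthetic life expectancy at birth in the high-70s (male) /
# low-80s (female), the order of magnitude of UK period life tables.
_MORTALITY_PARAMS = {"male": (2.0e-4, 2.6e-5, 0.098), "female": (1.2e-4, 1.35e-5, 0.102)}

# peak cause-specific fractions of all-cause mortality at old age
_CAUSE_PEAKS = {
    "male": {"IHD": 0.18, "ischemic_stroke": 0.05, "T2D": 0.015,
             "colorectal_cancer": 0.032, "lung_cancer": 0.060, "esophageal_cancer": 0.012},
    "female": {"IHD": 0.13, "ischemic_stroke": 0.06, "T2D": 0.015,
               "colorectal_cancer": 0.028, "lung_cancer": 0.045, "esophageal_cancer": 0.006},
}


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Age/sex population with all-cause and cause-specific mortality.

    Ages 0-100 per sex (top interval open-ended); smooth Gompertz-Makeham
    all-cause rates and normal-CDF age ramps for the six cause-specific
    fractions (their sum stays well below 1 at every age). Population counts
    get mild seeded noise; rates are deterministic given the config.
    """
    rng = np.random.default_rng(config.seed + 2)
    ages = np.arange(101)
    frames = []
    base_w = np.where(ages <= 60, 1.0, np.exp(-(ages - 60) / 15.0))
    for sex in ("male", "female"):
        a_mk, b_mk, g_mk = _MORTALITY_PARAMS[sex]
        m_all = a_mk + b_mk * np.exp(g_mk * ages)
        w = base_w * rng.lognormal(0.0, 0.03, len(ages))
        pop = w / w.sum() * (config.total_population / 2.0)
        frame = pd.DataFrame({"sex": sex, "age": ages, "population": pop,
                              "all_cause_rate": m_all})
        for outcome in OUTCOMES:
            ramp = norm.cdf((ages - 62.0) / 11.0)
            frame[outcome] = _CAUSE_PEAKS[sex][outcome] * ramp * m_all
        frames.append(frame)
    return validate_population(pd.concat(frames, ignore_index=True))


def generate_inputs(config: GeneratorConfig, out_dir: str | Path | None = None):
    """Generate the full input bundle (foods, trade, population).

    With ``out_dir`` set, writes ``foods.csv``, ``trade.csv``,
    ``population.csv``, a copy of the packaged ``exposure_response.csv`` and
    ``config.json``, each tagged with the generating seed.
    """
    foods = generate_food_table(config)
    trade = generate_trade_shares(config, foods)
    pop = generate_population(config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"fiveaday synthetic data; seed={config.seed} calibration={config.calibration}"
        write_foods_csv(foods, out / "foods.csv", header_comment=tag)
        write_trade_csv(trade, out / "trade.csv", header_comment=tag)
        with open(out / "population.csv", "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {tag}\n")
            pop.to_csv(fh, index=False)
        load_exposure_response().to_csv(out / "exposure_response.csv", index=False)
        (out / "config.json").write_text(json.dumps(asdict(config), indent=2))
    return foods, trade, pop
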