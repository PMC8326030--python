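# Methods

This note documents the model, its parameters and the design choices made
where the procedure was genuinely open, in the package's own terms.

## Pathway construction

The baseline diet is a national-average intake vector over 265
compositionally distinct food groups in eight categories (fruit,
vegetable, legume, red/processed meat, poultry, sweet snacks, other).
Each pathway proceeds in three deterministic stages:

1. **Proportional scaling.** Eligible groups (counting fruit/vegetable/
   legume groups in the pathway's increase set, UK-capable only for the
   *_UK pathways, zero-baseline groups frozen) are multiplied by a common
   factor *s* until the 5-a-day count reaches the 400-g target. The count
   is piecewise linear in *s* because legumes are capped at 80 g, so each
   linear piece is solved in closed form (no iteration; residuals are exact
   to float precision). Fruit juice and potatoes never count but keep
   their cost and footprints in diet totals.
2. **Per-kilocalorie substitution.** The energy added by fruit scaling
   displaces the sweet-snack pool; the energy added by vegetable+legume
   scaling displaces the meat pool (red + processed + poultry). Within a
   pool every food is scaled by the same factor, which removes energy in
   proportion to each food's baseline energy share. How the published
   analysis allocated the reduction within a pool is not stated; the
   proportional rule is scale-free, deterministic, and is the identity
   whenever the pool suffices. Pool floors are at zero: an exhausted pool
   releases its residual energy requirement to stage 3.
3. **Deviation-minimizing rebalance.** Total dietary energy is held at its
   baseline value (1744 kcal/person/day). Any residual imbalance is
   removed through the "other"-category foods by minimizing the total
   relative deviation Σ|xᵢ−bᵢ|/bᵢ, linearized with split nonnegative
   deviation variables and solved with HiGHS (`scipy.optimize.linprog`).
   Free foods may move in either direction, penalized symmetrically.
   Directly modified foods (all fruit and vegetables, sweet snacks, meat)
   are excluded from the objective. With the default calibrated inputs no
   pool is exhausted, the LP is trivially feasible with objective 0, and
   the optimum is unique because the pool reductions are fixed equalities.

Constraint residuals are checked at 1e-9; `status="infeasible"` identifies
the violated constraint family (empty eligible set, cap-bounded target, or
free-food energy balance).

## Health impact model

* **Exposure–response.** Thirteen risk–outcome pairs (packaged in
  `data/exposure_response.csv`): fruit (IHD 0.86, ischemic stroke 0.65,
  lung 0.93, esophageal 0.87 cancer, T2D 0.91 per 100-g increase),
  vegetables (IHD 0.86, stroke 0.87 per 100 g), legumes (IHD 0.76 per
  50 g), red meat (colorectal 0.86, T2D 0.80 per 100-g decrease) and
  processed meat (IHD 0.56, colorectal 0.85, T2D 0.58 per 50-g decrease),
  each with a 95% CI. Relations are log-linear, RR(Δ) = exp(βΔ) with
  β = ±ln(RR_unit)/unit; exposures acting on one disease multiply.
  Poultry changes carry no RR and are excluded; legume deltas are
  evaluated separately from other vegetables. Lung and esophageal cancer
  are applied to fruit only, exactly as tabulated.
* **Time lags.** RR(t) = exp(ln(RR_final)·w(t)) with w a normal CDF.
  Cardiometabolic: w(t) = Φ((t−5)/1.936); cancer: w(t) = 0 for t < 10,
  else Φ((t−20)/3.873). The endpoints (max effect at 10 y / 30 y, cancers
  unchanged for 10 y) are given; the normal's mean and sd are not, so the
  mean sits at the ramp midpoint and sd = ramp/5.164, making the weight
  ≈0.005 at the ramp start and ≈0.995 at its end. The cutoff below
  `zero_years` is strict (`t < zero_years`), so the cardiometabolic weight
  at t = 0 is the ~0.005 CDF tail, not an artificial zero. Applying the
  lag on the log-RR scale preserves multiplicativity.
* **Life table.** Annual cycles, ages 0–100 with an open-ended top
  interval, hazard→probability via q = 1−exp(−m), half-year person-year
  credit for within-year deaths. Cause-specific mortality is scaled by the
  lagged RRs and subtracted from all-cause mortality; baseline rates stay
  constant over follow-up and the diet is adopted instantly at t = 0.
  Population life-years gained age the current population forward with no
  births or migration; life expectancy at birth follows a birth cohort
  entering at t = 0 under the time-varying rates (expected life-years ÷
  cohort size). Default horizon 120 y so every cohort closes out.
* **Aggregation.** Life tables run per sex; the combined change in life
  expectancy weights males:females 105:100 at birth (configurable; a
  simple mean is also reported because the published weighting is not
  stated). The fruit-and-vegetable attribution reruns the model with meat
  deltas zeroed and reports the ratio of combined life-expectancy changes;
  it is undefined (None) when the full change is zero. Sensitivity bounds
  rerun with every RR at its lower (stronger protection) or upper (weaker)
  95% bound.

## Accounting

National aggregation multiplies per-capita daily deltas by 66.65 million
people and a 365-day year (no leap adjustment): kg CO2eq/d → Mt/y via
÷1e9, L/d → km³/y via ÷1e12. Percent changes and national totals are
always computed from unrounded internals — which is how a delta displayed
as −0.3 kg can coexist with a −4.1% change — and rounding (1 decimal for
kg/L/months, 2 for GBP, integer percents) is display-only.

## Synthetic inputs

The generator emulates the structure of the restricted survey inputs:

* **Foods.** 48 fruit (incl. one juice group), 64 vegetable (incl. three
  legume groups and one potato group) and 153 other groups (12 sweet
  snacks, 8 red meat, 8 processed meat, 4 poultry, 121 other). Intakes are
  log-normal (heavy-tailed: a few foods dominate each category, as in the
  published shares where bananas are 27% of fruit). The default "paper"
  calibration pins the published top-variety intakes (bananas 23.84 g,
  tomatoes 24.93 g, baked beans 15.47 g, ...) and classifies baked beans,
  other beans and lentils as legumes, reproducing the 19.5 g legume /
  120.5 g non-legume split of the 140-g vegetable baseline. Energy
  densities are uniform in category ranges (fruit 0.3–0.9, vegetables
  0.2–0.8, sweet snacks 3.5–5.5, meats 1.5–3.5 kcal/g); prices and
  footprint factors are log-normal around category means chosen so meat
  dominates GHGE. After drawing, counted fruit and vegetables are rescaled
  to 88 g and 140 g, remaining intakes to the 1744-kcal energy total, and
  prices/GHGE/WF factors to the £6.78 / 6.2 kg CO2eq / 611.4 L baseline
  aggregates — all multiplicative, so every target is hit exactly on every
  seed. UK-capable fruit and vegetables get lower energy density (×0.85),
  higher price (×1.3) and much lower blue water (×0.4), reproducing the
  published mechanisms (smaller substitutions and higher cost in the UK
  pathways; water savings from domestic varieties). The sweet-snack and
  meat pools (~250 and ~200 kcal/day) comfortably absorb the target-scale
  substitutions.
* **Trade shares.** Per fruit/vegetable group, a Dirichlet split over UK
  plus 1–3 foreign origins (~10% single-origin, ~10% with a GLOBAL
  fallback row). Origin factors are drawn so their share-weighted mean
  equals the food's factor exactly, with UK blue-water multipliers ~0.45
  vs ~1.4 foreign (UK production relies more on rainfall).
* **Population.** Ages 0–100 per sex, Gompertz–Makeham all-cause mortality
  m(a) = A + B·exp(g·a) tuned to a life expectancy at birth of ~78 y
  (male) / ~82 y (female); the six cause-specific fractions ramp with age
  by a normal CDF to peaks summing to ~0.33 of all-cause at old age. Counts
  total 66.65 M with a smooth age pyramid and mild seeded noise.

What the generator does **not** emulate: individual-level diaries and
survey weights, true per-food energy/price/footprint values (supplementary
data only; the ranges above are documented assumptions), within-category
correlation of prices and footprints, seasonality, and real UK age
structure. Pipeline results on synthetic inputs therefore demonstrate
correct mechanics and reproduce structural findings (pathway intakes and
orderings, attribution share, sign and rough size of footprint and
life-expectancy changes) but are not re-estimates of the published health
and footprint levels, which require the restricted inputs.

## Numerical and testing notes

* Scale factors solved in closed form; LP residual tolerance 1e-9;
  deterministic unique optimum on all shipped configurations.
* Constant-hazard life tables match 1/μ within the discretization error
  bound (0.5% at μ = 0.01); a 3-age toy population matches hand-enumerated
  survival arithmetic to 1e-12 relative.
* LP objectives are cross-checked against an exhaustive grid-search oracle
  on small instances (tolerance 1e-4).
* Default problem sizes (265 groups, 101 ages × 120 years, 20-seed
  sweeps) keep the full suite and the acceptance script in the
  seconds-to-a-minute range on one CPU.
* Baked beans count fully as legume toward the 80-g cap (the dish is
  majority white beans); the alternative — partial counting — is not
  supported.
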