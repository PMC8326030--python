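import pandas as pd
import pytest

import fiveaday as fa

_FOOD_DEFAULTS = dict(
    uk_capable=False,
    baseline_intake_g=0.0,
    energy_density_kcal_per_g=1.0,
    price_gbp_per_kg=1.0,
    ghge_kgco2e_per_kg=1.0,
    bluewf_l_per_kg=1.0,
)


def make_foods(rows):
    """Build a validated food table from terse row dicts (id/category + overrides)."""
    full = []
    for row in rows:
        r = dict(_FOOD_DEFAULTS)
        r.setdefault("counts_5aday", row.get("category") in ("fruit", "vegetable", "legume"))
        r.update(row)
        r.setdefault("name", r["id"])
        full.append(r)
    return fa.validate_foods(pd.DataFrame(full))


@pytest.fixture(scope="session")
def paper_inputs():
    """The calibrated synthetic fixture: foods, trade shares, population."""
    return fa.generate_inputs(fa.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def foods(paper_inputs):
    return paper_inputs[0]


@pytest.fixture(scope="session")
def trade(paper_inputs):
    return paper_inputs[1]


@pytest.fixture(scope="session")
def population(paper_inputs):
    return paper_inputs[2]


@pytest.fixture(scope="session")
def base_diet(foods):
    return fa.baseline_diet(foods)


@pytest.fixture(scope="session")
def pathway_results(foods, base_diet):
    """All four optimized pathways on the calibrated fixture."""
    return {
        pid: fa.build_and_solve_lp(base_diet, foods, spec)
        for pid, spec in fa.PATHWAYS.items()
    }
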