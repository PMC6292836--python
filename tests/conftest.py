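"""Shared fixtures: synthetic inventories and pipeline products.

Everything is generated programmatically at test time; the only shipped
data file is the national species table.
"""

from __future__ import annotations

import pandas as pd
import pytest

from sylvasim import carbon, scenarios, synthetic
from sylvasim.growth import (
    GrowthParams,
    SpeciesGrowth,
    build_regrowth_library,
)
from sylvasim.inventory_io import default_species_table
from sylvasim.management import classify


@pytest.fixture(scope="session")
def noise_free_inventory():
    """Noise-free single-species inventory with exact ground truth."""
    cfg = synthetic.noise_free_config(seed=11, n_plots=400)
    plots, trees, truth = synthetic.generate_inventory(cfg)
    return plots, trees, truth


@pytest.fixture(scope="session")
def species_table():
    return default_species_table()


def truth_growth_params(truth) -> GrowthParams:
    return GrowthParams({
        n: SpeciesGrowth(n, {"": s.a_intercept}, s.a_di, s.a_age, 0.0,
                         {"": s.b_intercept}, s.b_di, s.b_age, 0.0)
        for n, s in truth.species.items()
    })


@pytest.fixture(scope="session")
def legacy_fixture():
    """Classified legacy-stock inventory plus simulation inputs."""
    cfg = synthetic.legacy_config(seed=5, n_plots=1000)
    plots, trees, truth = synthetic.legacy_stock_inventory(cfg)
    classified = classify(plots, truth.thresholds)
    gp = truth_growth_params(truth)
    mr = {n: s.mortality for n, s in truth.species.items()}
    lib = build_regrowth_library(classified)
    return {
        "plots": classified,
        "trees": trees,
        "truth": truth,
        "gp": gp,
        "mr": mr,
        "lib": lib,
    }


@pytest.fixture(scope="session")
def scenario_ledgers(legacy_fixture, species_table):
    """Carbon ledgers of BaU and the three maximal intensification scenarios."""
    fx = legacy_fixture
    specs = {
        "BaU": scenarios.build_scenario("BaU"),
        "D": scenarios.build_scenario("D", 10),
        "M": scenarios.build_scenario("M", 10),
        "Ov": scenarios.build_scenario("O_v", 10),
    }
    return carbon.run_scenario_ledgers(
        fx["plots"], fx["gp"], fx["mr"], fx["truth"].thresholds, fx["lib"],
        specs, horizon=100, species_table=species_table,
    )
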