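import numpy as np
import pandas as pd
import pytest

from quantmg import pipeline as pl
from quantmg import synthetic_data as sd


@pytest.fixture(scope="session")
def small_scenario():
    """A small simulated study with materialized hit tables.

    One site per region, two years (10 samples), 12 families over 36 taxa,
    20k reads per sample, with nonzero annotation noise so the arbitration
    paths are exercised.
    """
    config = sd.SimConfig(
        n_families=12,
        n_taxa=36,
        n_sites_per_region=1,
        reads_per_sample=20_000,
        misannotation_rate=0.05,
        dual_hit_rate=0.05,
        seed=11,
    )
    return sd.simulate_scenario(config, emit_hits=True)


@pytest.fixture(scope="session")
def small_abundances(small_scenario):
    """Family-level volumetric abundance table for the small scenario."""
    return pl.scenario_abundances(small_scenario)


@pytest.fixture(scope="session")
def family_matrix(small_abundances):
    """Families x samples matrix of cells per liter."""
    return small_abundances.pivot(
        index="family", columns="sample_id", values="cells_per_L"
    )
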