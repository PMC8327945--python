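import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

# quiet the package's data-hygiene warnings during tests
logging.getLogger("karyoscale").setLevel(logging.ERROR)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def within_cells():
    """Within-species cell table with a planted exponent b = 0.58."""
    from karyoscale import simulate_within_species

    return simulate_within_species(
        b=0.58, log10_a=-0.6, n=1000, seed=42, dataset_id="fixture"
    )


@pytest.fixture(scope="session")
def small_among():
    """Small two-clade among-species dataset (tree, table, truth)."""
    from karyoscale import AmongSpeciesSimSpec, simulate_among_species

    spec = AmongSpeciesSimSpec(
        clades=("birds", "fish"), n_species_per_clade=20, seed=7
    )
    return simulate_among_species(spec)


@pytest.fixture(scope="session")
def selection_data():
    """Default-condition selection experiment (table, truth)."""
    from karyoscale import SelectionSimSpec, simulate_selection_experiment

    return simulate_selection_experiment(SelectionSimSpec(seed=5))
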