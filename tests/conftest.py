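"""Shared fixtures: phantoms, solved fields and the study population table.

Heavy objects are session-scoped so the expensive pieces (the 20-subject
population run, the 2 mm reference solve) are computed once per test run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tdcsim import (
    PhantomSpec,
    build_phantom,
    build_study_montage,
    locate_1010,
    sample_population,
    solve_montage,
)
from tdcsim.study import run_study

# fixed seed defining the test population; the study conditions themselves
# (sample sizes, variability ranges, 2 mA, 2 mm grids) live in the package
# defaults
POPULATION_SEED = 42
POPULATION_N = 20

# montages the population criteria need: the five electrode-position
# configurations, the four size variants and the four added distance variants
# (the distance baseline reuses APPS, solved once)
STUDY_MONTAGES = (
    "BILAT_M1", "M1_SO", "HD", "LRPS", "APPS",
    "APPS_1X1", "APPS_3X3", "APPS_5X5", "APPS_7X5",
    "APPS_P2", "APPS_P4", "APPS_P6", "APPS_P8",
)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Unperturbed default 5-shell sphere at 2 mm."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    """Cheap 4 mm phantom for metric plumbing tests."""
    return build_phantom(PhantomSpec(voxel_size_mm=4.0))


@pytest.fixture(scope="session")
def eeg_map(sphere_phantom):
    return locate_1010(sphere_phantom)


@pytest.fixture(scope="session")
def coarse_eeg(coarse_phantom):
    return locate_1010(coarse_phantom)


@pytest.fixture(scope="session")
def apps_solution(sphere_phantom, eeg_map):
    """APPS montage solved at 2 mm, scaled to 2 mA."""
    m = build_study_montage("APPS", sphere_phantom, eeg_map)
    return solve_montage(sphere_phantom, m)


@pytest.fixture(scope="session")
def study_table():
    """Population study: 20 phantoms x 13 unique montage configurations.

    The Round-3 baseline (APPS_P0) is geometrically identical to APPS, so its
    rows are copies of the APPS rows with the Round-3 tag.
    """
    population = sample_population(POPULATION_N, seed=POPULATION_SEED)
    table = run_study(population, montages=STUDY_MONTAGES)
    p0 = table[table.montage_name == "APPS"].copy()
    p0["montage_name"] = "APPS_P0"
    p0["round_tag"] = "round3"
    return pd.concat([table, p0], ignore_index=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
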