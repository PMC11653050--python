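"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycowear import synthetic as syn
from glycowear.excursion import build_design_table


@pytest.fixture(scope="session")
def small_raw_config() -> syn.SimulationConfig:
    """Two participants, one shortened day: keeps native-rate files small."""
    return syn.SimulationConfig(
        n_participants=2, days_range=(1, 1), day_seconds=6 * 3600.0, seed=7
    )


@pytest.fixture(scope="session")
def grid_cohort() -> syn.GridCohort:
    """Two full-length participants at the 5-min grid level."""
    return syn.simulate_grid_cohort(
        syn.SimulationConfig(n_participants=2, days_range=(3, 3), seed=11)
    )


@pytest.fixture(scope="session")
def rolled_grids(grid_cohort) -> dict[str, pd.DataFrame]:
    return syn.attach_rolling(grid_cohort.grids)


@pytest.fixture(scope="session")
def design_table(grid_cohort, rolled_grids):
    design, audit = build_design_table(
        rolled_grids, grid_cohort.meals, grid_cohort.participants
    )
    return design


def make_grid(times_s, glucose, **channels) -> pd.DataFrame:
    """Hand-built aligned-grid frame for toy tests."""
    df = pd.DataFrame({"time": np.asarray(times_s, dtype=float)})
    df["glucose"] = np.asarray(glucose, dtype=float)
    for name, vals in channels.items():
        df[name] = np.asarray(vals, dtype=float)
    return df
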