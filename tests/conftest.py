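import numpy as np
import pandas as pd
import pytest

from twindti.cohort import (
    SimulationConfig,
    build_roster,
    retained_pairs,
    roster_to_frame,
    simulate_regional_values,
)


REGIONS_8 = ("gCC", "bCC", "sCC", "CST_R", "CST_L", "SLF_R", "SLF_L", "EC_R")


@pytest.fixture(scope="session")
def small_cohort():
    """200-pair, 8-region cohort with batch and covariate effects."""
    cfg = SimulationConfig(
        n_mz=100,
        n_dz=100,
        components_by_region={r: ("ACE", 0.5, 0.2, 0.0, 0.3) for r in REGIONS_8},
        metrics=("FA", "MD"),
        seed=11,
    )
    roster = build_roster(cfg)
    table = simulate_regional_values(roster, cfg)
    frame = roster_to_frame(retained_pairs(roster))
    return cfg, frame, table


@pytest.fixture(scope="session")
def null_batch_cohort():
    """200-pair cohort with two scanner labels but zero batch effect."""
    cfg = SimulationConfig(
        n_mz=100,
        n_dz=100,
        components_by_region={r: ("ACE", 0.5, 0.2, 0.0, 0.3) for r in REGIONS_8},
        metrics=("FA",),
        batch_effects={"site_A": (0.0, 1.0), "site_B": (0.0, 1.0)},
        seed=13,
    )
    roster = build_roster(cfg)
    table = simulate_regional_values(roster, cfg)
    frame = roster_to_frame(retained_pairs(roster))
    return cfg, frame, table


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def feature_matrix(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    sub = table[table["metric"] == metric]
    return sub.pivot_table(index="region", columns="subject_id", values="value", dropna=False)
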