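import numpy as np
import pandas as pd
import pytest

from adgrs.io import (
    CohortPanel,
    GenotypeMatrix,
    RiskWeight,
    WeightTable,
    default_weight_table,
)
from adgrs.simulate import SimulationParams, simulate_study


@pytest.fixture(scope="session")
def weights() -> WeightTable:
    return default_weight_table()


@pytest.fixture(scope="session")
def tiny_weights() -> WeightTable:
    """Two-locus table with simple betas for hand arithmetic."""
    return WeightTable(
        weights=(
            RiskWeight("rs_a", "A", 0.5),
            RiskWeight("rs_b", "C", -0.2),
        )
    )


@pytest.fixture()
def tiny_genotypes() -> GenotypeMatrix:
    return GenotypeMatrix(
        dosages=pd.DataFrame(
            {"rs_a": [2.0, 0.0, 1.0], "rs_b": [1.0, 0.0, np.nan]},
            index=["p1", "p2", "p3"],
        )
    )


@pytest.fixture(scope="session")
def small_study(weights) -> "SyntheticStudy":
    """A modest synthetic cohort shared by read-only tests."""
    params = SimulationParams(n_persons=1500, seed=42)
    return simulate_study(params, weights)


def make_panel_frame(**overrides) -> pd.DataFrame:
    """A minimal valid 2-person, 3-wave panel frame."""
    base = pd.DataFrame(
        {
            "person_id": ["a", "a", "a", "b", "b", "b"],
            "wave_year": [2006, 2008, 2010] * 2,
            "race": ["NHW"] * 3 + ["NHB"] * 3,
            "sex": ["male"] * 3 + ["female"] * 3,
            "age": [70.0, 72.0, 74.0, 66.0, 68.0, 70.0],
            "dementia_prob": [0.0, 1.0, 0.5, 0.2, np.nan, np.nan],
            "memory_score": [1.0, 0.9, 0.8, 0.5, 0.4, np.nan],
            "status": ["observed"] * 4 + ["nonresponse", "dead"],
        }
    )
    for key, value in overrides.items():
        base[key] = value
    return base


@pytest.fixture()
def panel_frame() -> pd.DataFrame:
    return make_panel_frame()


@pytest.fixture()
def panel(panel_frame) -> CohortPanel:
    return CohortPanel(data=panel_frame)
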