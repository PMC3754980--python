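import numpy as np
import pandas as pd
import pytest

from mzmwas.containers import FeatureTable
from mzmwas.synthetic_cohort import (
    SimulationConfig,
    simulate_dataset,
    synthetic_metabolite_db,
)


@pytest.fixture(scope="session")
def small_table() -> FeatureTable:
    """3 features x 4 samples with one missing value."""
    fids = ["100.00000@10.00", "200.00000@20.00", "300.00000@30.00"]
    data = pd.DataFrame(
        [[10.0, 12.0, 9.0, 11.0], [5.0, np.nan, 6.0, 7.0], [1.0, 2.0, 3.0, 4.0]],
        index=fids,
        columns=["s1", "s2", "s3", "s4"],
    )
    return FeatureTable(
        data=data,
        mz=pd.Series([100.0, 200.0, 300.0], index=fids),
        rt=pd.Series([10.0, 20.0, 30.0], index=fids),
    )


@pytest.fixture(scope="session")
def four_samples() -> pd.DataFrame:
    return pd.DataFrame(
        {"group": ["case", "case", "control", "control"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )


@pytest.fixture(scope="session")
def synthetic_db():
    return synthetic_metabolite_db(n_records=300, seed=11)


@pytest.fixture(scope="session")
def simulated(synthetic_db):
    """A 45-sample cohort with strong planted effects (shared across tests)."""
    cfg = SimulationConfig(
        n_chemicals=120,
        differential_fraction=0.1,
        effect_size_log2=2.0,
        sigma_adduct=0.1,
        seed=42,
    )
    table, samples, truth = simulate_dataset(cfg, synthetic_db)
    return cfg, table, samples, truth
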