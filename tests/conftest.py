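import numpy as np
import pandas as pd
import pytest

import clonotrack as ct


@pytest.fixture(scope="session")
def small_cohort() -> ct.SyntheticCohort:
    """A compact cohort with every arm generated, shared across tests."""
    cfg = ct.CohortConfig(
        n_patients=6,
        n_genes=60,
        n_cells_per_sample=150,
        n_spatial_cells=400,
        seed=1234,
    )
    return ct.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_config(small_cohort) -> ct.CohortConfig:
    return small_cohort.config


@pytest.fixture
def toy_survival() -> pd.DataFrame:
    """Ten subjects, two groups, mixed censoring, no ties."""
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(10)],
            "time_days": [3.0, 5.0, 7.0, 2.0, 11.0, 9.0, 4.0, 6.0, 8.0, 10.0],
            "event": [1, 1, 0, 1, 1, 1, 0, 1, 1, 0],
            "group": ["a"] * 5 + ["b"] * 5,
        }
    )


def truth_bcr_counts(cohort: ct.SyntheticCohort) -> pd.Series:
    """Planted per-sample unique-BCR counts from the cohort truth."""
    counts = {}
    for pid, info in cohort.truth["patients"].items():
        counts[f"{pid}_pre"] = info["bcr_pre"]
        counts[f"{pid}_post"] = info["bcr_post"]
    return pd.Series(counts)


def csr_map(n: int, seed: int, field: float = 1000.0,
            types=("A", "B", "C", "D"), probs=None) -> pd.DataFrame:
    """Complete-spatial-randomness map with independently scattered types."""
    rng = np.random.default_rng(seed)
    probs = probs if probs is not None else np.full(len(types), 1 / len(types))
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "x_um": rng.uniform(0, field, n),
            "y_um": rng.uniform(0, field, n),
            "cell_type": [types[i] for i in rng.choice(len(types), n, p=probs)],
            "compartment": "tumor",
            "treated": True,
        }
    )
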