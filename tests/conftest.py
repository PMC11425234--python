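import numpy as np
import pandas as pd
import pytest

from masldstage import GenConfig, generate_human_cohorts, make_ortholog_map


@pytest.fixture(scope="session")
def small_cfg() -> GenConfig:
    return GenConfig(n_genes=300, n_cohorts=2, samples_per_cohort=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """One small generated human dataset shared across read-only tests."""
    counts, samples, truth = generate_human_cohorts(small_cfg)
    orth = make_ortholog_map(counts.index, coverage=0.85, seed=12)
    return counts, samples, truth, orth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_samples() -> pd.DataFrame:
    """Twelve graded human samples across two batches."""
    n = 12
    rs = np.random.default_rng(5)
    nas = rs.integers(0, 9, n).astype(float)
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "batch": ["b1"] * 6 + ["b2"] * 6,
        "sex": ["M", "F"] * 6,
        "species": "human",
        "nas": nas,
        "fibrosis": np.clip(np.rint(nas / 2), 0, 4),
        "group": "clinical",
    }).set_index("sample_id", drop=False)
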