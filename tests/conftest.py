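import numpy as np
import pandas as pd
import pytest

from genebankqc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def balanced_grid():
    """12 accessions x 6 years, complete, homoscedastic; with the grid array."""
    rng = np.random.default_rng(42)
    a_n, b_n = 12, 6
    g = rng.normal(0, 3, a_n)
    a = rng.normal(0, 5, b_n)
    e = rng.normal(0, 2, (a_n, b_n))
    y = 50 + g[:, None] + a[None, :] + e
    records = pd.DataFrame({
        "accession_id": np.repeat([f"A{i:02d}" for i in range(a_n)], b_n),
        "year": np.tile(np.arange(2000, 2000 + b_n), a_n),
        "trait": "FT",
        "value": y.ravel(),
        "replicate_index": 1,
    })
    return records, y


@pytest.fixture
def small_dataset():
    """Seeded non-orthogonal dataset at the study-condition magnitudes."""
    cfg = SimulationConfig(n_accessions=120, n_years=15, obs_per_accession=4,
                           seed=7)
    return simulate_dataset(cfg)


def balanced_anova_components(y: np.ndarray):
    """Expected-mean-squares estimators for a complete two-way grid."""
    a_n, b_n = y.shape
    ms_a = b_n * np.var(y.mean(axis=1), ddof=1)
    ms_b = a_n * np.var(y.mean(axis=0), ddof=1)
    resid = y - y.mean(1, keepdims=True) - y.mean(0, keepdims=True) + y.mean()
    ms_e = (resid ** 2).sum() / ((a_n - 1) * (b_n - 1))
    return (ms_a - ms_e) / b_n, (ms_b - ms_e) / a_n, ms_e
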