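import numpy as np
import pandas as pd
import pytest

from otubench import CountMatrix, random_preset, simulate_dataset


@pytest.fixture
def small_counts() -> CountMatrix:
    """Deterministic 8×6 integer table with two groups, staggered zeros."""
    rng = np.random.default_rng(42)
    arr = rng.integers(0, 50, size=(8, 6)).astype(float)
    arr[rng.random(arr.shape) < 0.25] = 0
    arr[0] += 1  # keep at least one feature positive everywhere
    samples = [f"S{j}" for j in range(6)]
    df = pd.DataFrame(arr, index=[f"F{i}" for i in range(8)], columns=samples)
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
    return CountMatrix(df, groups=groups, layer="raw")


@pytest.fixture(scope="session")
def reduced_dataset():
    """Scenario-1-like reduced simulation: 4 groups × 5 replicates × 300
    features, 40% structural zeros, depths 5000–20000, pool 10× max depth."""
    preset = random_preset(
        n_conditions=4,
        n_features=300,
        structural_zero_frac=0.40,
        variability=0.25,
        depth_range=(5_000, 20_000),
        replicates_per_condition=5,
        intensity_sigma=2.5,
        seed=7,
    )
    return simulate_dataset(preset)
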