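import numpy as np
import pandas as pd
import pytest

from cnfc import ExpressionMatrix, SyntheticSpec, simulate_development


@pytest.fixture
def small_counts() -> ExpressionMatrix:
    """3-gene x 4-sample counts matrix with two groups."""
    values = pd.DataFrame(
        [[10.0, 12, 40, 38], [5, 6, 5, 7], [0, 1, 0, 0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame({"group": ["ref", "ref", "trt", "trt"]}, index=values.columns)
    return ExpressionMatrix(values=values, scale="counts", meta=meta)


@pytest.fixture
def log_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.normal(8, 2, size=(20, 6)),
        index=[f"g{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3}, index=values.columns)
    return ExpressionMatrix(values=values, scale="log_intensity", meta=meta)


@pytest.fixture(scope="session")
def dev_dataset():
    """Default development simulation, shared across tests (read-only)."""
    return simulate_development(SyntheticSpec(seed=3))
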