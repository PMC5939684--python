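import numpy as np
import pandas as pd
import pytest

from mirlag.preprocessing import DetectionCalls, ExpressionMatrix
from mirlag.synthetic_data import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but fully featured study design for fast end-to-end tests."""
    return SimulationConfig(
        n_mirna=40,
        n_mrna=80,
        frac_groupA=0.1,
        frac_groupB=0.1,
        targets_per_mirna=3,
        frac_background=0.2,
        false_prediction_rate=0.01,
        n_planted_terms=2,
        n_decoy_terms=5,
        term_size=6,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_expression(small_config)


def make_matrix(values: np.ndarray, feature_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n)]
    if sample_ids is None:
        assert s % 2 == 0
        half = s // 2
        sample_ids = [f"rd10_P15_{r}" for r in range(1, half + 1)] + [f"WT_P15_{r}" for r in range(1, s - half + 1)]
    return ExpressionMatrix(pd.DataFrame(values, index=feature_ids, columns=sample_ids))


def make_calls(matrix: ExpressionMatrix, present: np.ndarray) -> DetectionCalls:
    return DetectionCalls(pd.DataFrame(np.asarray(present, dtype=bool), index=matrix.values.index, columns=matrix.values.columns))
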