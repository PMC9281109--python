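import numpy as np
import pandas as pd
import pytest

from trajspur.panel import LongitudinalPanel
from trajspur.scenarios import ScenarioConfig


def make_panel(Y: np.ndarray, times=None, true_group=None) -> LongitudinalPanel:
    """Build a balanced panel from an (N, t) array of measurements."""
    Y = np.asarray(Y, dtype=float)
    N, t = Y.shape
    times = np.arange(1, t + 1, dtype=float) if times is None else np.asarray(times, float)
    df = pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(1, N + 1), t),
            "occasion": np.tile(np.arange(1, t + 1), N),
            "time": np.tile(times, N),
            "y": Y.ravel(),
        }
    )
    if true_group is not None:
        df["true_group"] = np.repeat(np.asarray(true_group), t)
    return LongitudinalPanel(df)


@pytest.fixture
def two_line_config() -> ScenarioConfig:
    """Two widely separated linear groups, modest noise."""
    return ScenarioConfig(
        scenario_id=1,
        n=200,
        t=5,
        group_weights=np.array([0.6, 0.4]),
        mean_coefficients=[np.array([0.0, 2.0]), np.array([20.0, -1.0])],
        random_intercept=[{"dist": "normal", "sd": 0.2}] * 2,
        residual_sd=np.full((2, 5), 0.5),
        seed=11,
    )


@pytest.fixture
def tiny_panel() -> LongitudinalPanel:
    """3 subjects x 4 occasions with distinct patterns."""
    rng = np.random.default_rng(5)
    Y = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [8.0, 7.5, 7.2, 6.8],
            [4.0, 4.1, 3.9, 4.2],
        ]
    ) + 0.05 * rng.standard_normal((3, 4))
    return make_panel(Y)
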