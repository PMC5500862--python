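import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from hetsurv import SimulationConfig, SurvivalCohort, simulate_cohort


@pytest.fixture
def toy_cohort():
    """Six-sample mixed-type cohort, no missing values."""
    frame = pd.DataFrame(
        {
            "age": [55.0, 62.0, 47.0, 70.0, 58.0, 66.0],
            "stage": ["I", "II", "III", "II", "I", "III"],
        }
    )
    time = np.array([100.0, 250.0, 90.0, 400.0, 310.0, 150.0])
    event = np.array([1, 0, 1, 0, 1, 1])
    return SurvivalCohort(frame=frame, time=time, event=event)


@pytest.fixture(scope="session")
def signal_cohort():
    """Simulated cohort with a strong single-feature signal; reused by the
    orientation-contract and selection tests."""
    cfg = SimulationConfig(
        n_samples=150,
        n_continuous=3,
        nominal_levels=(2,),
        ordinal_levels=(),
        coefficients=(1.5, 0.0, 0.0, 0.3),
        seed=42,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohorts():
    """Train/test pair from the same data-generating process."""
    base = SimulationConfig(n_samples=300, seed=7)
    train, train_truth = simulate_cohort(base)
    test, test_truth = simulate_cohort(
        SimulationConfig(n_samples=150, seed=8)
    )
    return (train, train_truth), (test, test_truth)
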