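import numpy as np
import pandas as pd
import pytest

from bearacc import synthetic as syn

#: Printed confusion matrix of the captive-bear forest (rows observed
#: feeding/resting/running/walking, columns predicted in the same order).
CAPTIVE_CONFUSION = np.array(
    [
        [3826, 195, 0, 104],
        [103, 6640, 0, 15],
        [0, 0, 145, 3],
        [154, 5, 1, 1688],
    ]
)


@pytest.fixture(scope="session")
def training_windows() -> pd.DataFrame:
    """Class-balanced labelled windows from the default simulator (shared)."""
    return syn.simulate_labeled_windows(500, seed=101)


@pytest.fixture(scope="session")
def heldout_windows() -> pd.DataFrame:
    return syn.simulate_labeled_windows(200, seed=202)


@pytest.fixture(scope="session")
def day_schedule():
    """One simulated day with the default crepuscular diel profile."""
    return syn.simulate_schedule(duration=86400.0, seed=7)


@pytest.fixture(scope="session")
def continuous_series() -> pd.DataFrame:
    """A noisy continuous multi-behaviour stream for feature-chain tests."""
    sch = syn.simulate_schedule(duration=900.0, seed=31)
    return syn.simulate_accel(sch, seed=32).drop(columns="label")
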