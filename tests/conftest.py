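import numpy as np
import pandas as pd
import pytest

from netguide.ctvar import DriftModel
from netguide.ema import EMASeries, default_registry
from netguide.synth import default_truth


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def truth(registry):
    return default_truth(registry)


@pytest.fixture
def chain3():
    """Unidirectional 3-node chain 1 -> 2 -> 3 with unit couplings and
    unit decay: closed-form effect matrices via the nilpotent series."""
    A = np.array([[-1.0, 0.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    return DriftModel(names=("n1", "n2", "n3"), A=A, mu=np.zeros(3),
                      Q=np.eye(3), R=np.zeros(3))


@pytest.fixture
def twonode():
    A = np.array([[-1.0, 0.0], [0.5, -1.0]])
    return DriftModel(names=("n1", "n2"), A=A, mu=np.array([10.0, 20.0]),
                      Q=2.0 * np.eye(2), R=np.zeros(2))


def make_series(values: dict, times=None, phases=None, participant="p1") -> EMASeries:
    """Small EMASeries builder for tests."""
    n = len(next(iter(values.values())))
    times = np.arange(n, dtype=float) if times is None else np.asarray(times, float)
    phases = ["baseline"] * n if phases is None else list(phases)
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in values.items()},
                      index=times)
    return EMASeries(participant=participant, data=df,
                     phase=pd.Series(phases, index=times))


@pytest.fixture
def series_builder():
    return make_series
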