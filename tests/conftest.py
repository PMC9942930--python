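import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import fluctest as ft


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fig4_model():
    """The benchmark switching regime: f=0.1, kx=1, k2=1/5 (Z=4.5)."""
    return ft.SwitchingModel(k1=1.0 / 45.0, k2=0.2, kx=1.0)


@pytest.fixture
def exp_cycle():
    return ft.CellCycleModel(family="exponential", mean_cycle=1.0)


def make_dataset(fractions, t=5.0, scale=10**6):
    """Dataset whose colony fractions approximate the given values."""
    fr = np.asarray(fractions, dtype=float)
    n_total = np.full(fr.size, scale, dtype=np.int64)
    n_state2 = np.rint(fr * scale).astype(np.int64)
    return ft.FluctuationDataset(t=t, n_total=n_total, n_state2=n_state2)
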