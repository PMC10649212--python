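import numpy as np
import pandas as pd
import pytest

from broilerenv.schedule import build_schedule
from broilerenv import synthetic as syn


@pytest.fixture(scope="session")
def schedule():
    """Default brooding schedule: 30 degC at day 0 to 21 degC at day 27."""
    return build_schedule()


@pytest.fixture(scope="session")
def flat_schedule():
    """Constant 25 degC schedule - convenient for hand-counted exposure."""
    return build_schedule(((0, 25.0), (35, 25.0)))


def make_series(t, rh=60.0, start_hour=0):
    """Aligned series frame from plain temperature (and RH) arrays."""
    t = np.asarray(t, dtype=float)
    rh = np.broadcast_to(np.asarray(rh, dtype=float), t.shape)
    hours = np.arange(start_hour, start_hour + t.size)
    return pd.DataFrame({
        "hour_of_age": hours,
        "age_day": hours // 24,
        "t": t,
        "rh": rh,
    })


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small but complete synthetic study shared across tests."""
    cfg = syn.GeneratorConfig(n_flocks=12, n_farms=6, seed=7, fault_rate=0.0)
    return syn.generate(cfg)
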