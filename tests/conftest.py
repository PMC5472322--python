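import numpy as np
import pytest

from anacap import BreathSeries, make_participant


@pytest.fixture
def truth():
    """A reference synthetic participant (deterministic)."""
    return make_participant(7)


@pytest.fixture
def noiseless_truth(truth):
    import dataclasses

    return dataclasses.replace(truth, noise_sd=0.0)


def constant_series(value=2.0, duration=120.0, dt=2.0, power=None):
    t = np.arange(dt, duration + dt / 2, dt)
    kwargs = {}
    if power is not None:
        kwargs["power"] = np.full_like(t, float(power))
    return BreathSeries(t=t, vo2=np.full_like(t, value), vco2=0.85 * np.full_like(t, value), **kwargs)


@pytest.fixture
def make_constant_series():
    return constant_series
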