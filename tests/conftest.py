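import numpy as np
import pytest

from pulsetrain import PulseSeries, db_to_linear

THRESHOLD_PA = db_to_linear(139.0)


def random_pulse_tuples(rng, n_max=40):
    """Random valid pulse list exercising reflections, gaps and all criteria.

    Times are multiples of 0.5 ms with gaps drawn from a mixture of
    reflection-scale (< 2 ms), click-scale and event-splitting scales;
    pressures sit above the detection threshold; ratios and arrival-time
    differences are broad.  Returns ``(t, spl_a, spl_b, td)`` tuples.
    """
    n = int(rng.integers(2, n_max + 1))
    scales = rng.choice([1.0, 30.0, 250.0], size=n - 1, p=[0.2, 0.6, 0.2])
    gaps = np.maximum(np.round(rng.exponential(scales) * 2.0) / 2.0, 0.5)
    t = np.concatenate(([0.0], np.cumsum(gaps)))
    spl_a = rng.uniform(THRESHOLD_PA * 1.01, 80.0, n)
    splr = rng.uniform(0.3, 1.4, n)
    spl_b = np.maximum(spl_a / splr, THRESHOLD_PA * 1.01)
    td = np.round(rng.uniform(-500.0, 500.0, n) * 4.0) / 4.0
    return list(zip(t.tolist(), spl_a.tolist(), spl_b.tolist(), td.tolist()))


def series_from_tuples(pulses, **kwargs):
    arr = np.asarray(pulses, dtype=float)
    return PulseSeries(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


def constant_train(n=10, interval_ms=10.0, spl_a=20.0, splr=1.0, td_us=50.0, t0=0.0):
    """Perfectly regular train: constant interval, SPL, ratio and td."""
    t = t0 + np.arange(n) * interval_ms
    a = np.full(n, spl_a)
    return PulseSeries(t, a, a / splr, np.full(n, td_us))
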