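import numpy as np
import pytest

import iscatml as m


@pytest.fixture(scope="session")
def fixtures():
    """Canonical small simulated datasets shared across the suite."""
    return m.make_fixtures(seed=202)


@pytest.fixture(scope="session")
def bg_ratio(fixtures):
    """Ratiometric stack of the background-only fixture."""
    from iscatml.dra import differential_rolling_average
    return differential_rolling_average(fixtures["background"], fixtures["dra"])


def make_tent(depth, window, baseline=0.0, vertex=0):
    """Exact noise-free V/tent trace of a landing transient."""
    t = np.arange(vertex - window, vertex + window + 1)
    values = baseline - depth * np.clip(1.0 - np.abs(t - vertex) / window, 0, None)
    return m.ContrastTrace(frames=t, values=values)
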