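"""Shared fixtures and generators for the test suite.

All random fixtures are seeded; hypothesis runs derandomized so the suite
is bit-stable across runs.
"""

from datetime import datetime

import numpy as np
import pytest
from hypothesis import settings

from photobeam import ActivityTrace

settings.register_profile("stable", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("stable")

T0 = datetime(2022, 1, 1, 8, 0, 0)


def random_valid_trace(rng, fly_id="f1", duration=400, n_beams=17,
                       zt0=0.0, activity=0.5):
    """A random trace satisfying the displacement invariant by construction:
    counts are net beam displacement plus Poisson extra crossings."""
    pos = np.empty(duration, dtype=np.int64)
    pos[0] = rng.integers(1, n_beams + 1)
    steps = rng.integers(-3, 4, duration - 1)
    for k in range(1, duration):
        pos[k] = min(max(pos[k - 1] + steps[k - 1], 1), n_beams)
    counts = np.abs(np.diff(pos, prepend=pos[0]))
    counts = counts + rng.poisson(activity, duration)
    return ActivityTrace(fly_id=fly_id, t0=T0, zt0=zt0, counts=counts,
                         position=pos)


@pytest.fixture
def rng():
    return np.random.default_rng(20220)
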