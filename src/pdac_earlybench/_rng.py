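"""Counter-based pseudo-random numbers for the simulation kernels.

Each simulated person gets an independent splitmix64 stream keyed on
(seed, stream tag, person id), so histories are reproducible and
independent of iteration order or batching.  splitmix64 passes BigCrush
and is the standard seeding generator of the xoshiro family; the
per-draw cost is a handful of integer operations, which matters inside
the person-month loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_U53 = np.float64(1.0 / 9007199254740992.0)  # 2**-53


@njit(cache=True, inline="always")
def stream_key(seed, tag, person):
    """Initial splitmix64 state for one person's stream."""
    x = (np.uint64(seed) + np.uint64(1)) * _MIX1
    x ^= (np.uint64(tag) + np.uint64(1)) * _MIX2
    x ^= np.uint64(person) * _GOLDEN
    return x


@njit(cache=True, inline="always")
def next_state(x):
    return x + _GOLDEN


@njit(cache=True, inline="always")
def uniform(x):
    """Advance the state and return (new_state, U(0,1) double)."""
    x = x + _GOLDEN
    z = x
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    z = z ^ (z >> np.uint64(31))
    return x, np.float64(z >> np.uint64(11)) * _U53
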