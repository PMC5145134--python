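"""Reproducible random streams.

Every stochastic solver draws from a counter-based Philox generator.  The
stream for replicate ``r`` of a run seeded with ``seed`` is derived as
``Philox(SeedSequence(entropy=seed, spawn_key=(r,)))``, so ensembles are
bitwise reproducible regardless of scheduling or replicate order.
Exponential waiting times are sampled by inverse transform,
``-log1p(-u)/rate`` with ``u`` uniform on [0, 1).
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["stream", "exponential"]


def stream(seed: int, replicate: int = 0) -> np.random.Generator:
    """The documented (seed, replicate) -> generator derivation."""
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence(entropy=seed, spawn_key=(replicate,)))
    )


def exponential(rng: np.random.Generator, rate: float) -> float:
    """Exp(rate) waiting time via inverse transform of a uniform draw."""
    return -math.log1p(-rng.random()) / rate
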