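"""Shared fixtures.

The miniature-study runs are expensive (seconds to tens of seconds each),
so they are computed once per session and shared between the trend,
acceptance and mean-field-comparison tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from nanogelmc.study import run_miniature

MINI_EQUIL = 40_000
MINI_PROD = 20_000
MINI_SEED = 1


@pytest.fixture(scope="session")
def mini_runs():
    """Production summaries of the scaled-down study systems.

    Keys: (charged_per_chain, temperature_celsius, n_nanoparticles).
    Covers low/high network charge, cold/hot, with and without
    nanoparticles.
    """
    combos = [
        (1, 20, 0),
        (1, 64, 0),
        (3, 20, 0),
        (3, 64, 0),
        (1, 20, 4),
        (1, 64, 4),
        (3, 20, 4),
        (3, 64, 4),
    ]
    return {
        key: run_miniature(
            charged_per_chain=key[0],
            temperature_celsius=key[1],
            n_nanoparticles=key[2],
            seed=MINI_SEED,
            n_equilibration=MINI_EQUIL,
            n_production=MINI_PROD,
        )
        for key in combos
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
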