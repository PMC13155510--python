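"""Shared fixtures: scaled engine profile and one cached burn-in tumor state.

The burn-in (4 stem cells grown drug-free to the standardized density 0.58)
is the common initial condition of every treatment experiment, exactly as a
single saved tumor state is reused across experiments in practice; it is
session-scoped because it costs a few seconds to grow.
"""

from __future__ import annotations

import numpy as np
import pytest

from gliomarl import EngineParams, grow_initial_tme
from gliomarl.surrogate import SurrogateParams

BURNIN_SEED = 12345


@pytest.fixture(scope="session")
def scaled_params() -> EngineParams:
    return EngineParams.scaled()


@pytest.fixture(scope="session")
def burnin_tme(scaled_params):
    return grow_initial_tme(scaled_params, seed=BURNIN_SEED)


@pytest.fixture(scope="session")
def surrogate_params() -> SurrogateParams:
    return SurrogateParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
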