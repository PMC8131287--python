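"""Shared fixtures.

The two replica-exchange pipeline runs (bidirectional, integrated-mode
dG_REUS; unidirectional, depth-mode) are session-scoped: they are the
expensive part of the suite and several acceptance checks read different
aspects of the same run (exchange statistics, PMF, assembled free energy).
Run lengths are scaled to a single CPU (3,000 / 2,500 cycles standing in for
the production 10-20 ns per replica); all seeds are fixed.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from reusbind.corrections import TISchedule
from reusbind.pipeline import RunConfig, WHAMConfig, run_pipeline
from reusbind.restraints import build_window_ladder
from reusbind.reus import REUSConfig
from reusbind.toy_system import ToySystem

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def system() -> ToySystem:
    return ToySystem()


@pytest.fixture(scope="session")
def ladder(system):
    return build_window_ladder()


@pytest.fixture(scope="session")
def bi_pipeline():
    """Bidirectional run, integrated-mode dG_REUS (end-to-end oracle mode)."""
    cfg = RunConfig(
        reus=REUSConfig(n_cycles=3000, steps_per_cycle=20, seed=0),
        wham=WHAMConfig(mode="integrated", n_boot=15),
        ti=TISchedule(equil_steps=2000, prod_steps=8000),
        seed=1,
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def uni_pipeline():
    """Unidirectional run (ladder truncated at the bound center), depth mode."""
    cfg = RunConfig(
        reus=REUSConfig(n_cycles=2500, steps_per_cycle=20, seed=0),
        wham=WHAMConfig(mode="depth", n_boot=10),
        ti=TISchedule(equil_steps=2000, prod_steps=8000),
        direction="unidirectional",
        seed=3,
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
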