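"""Shared fixtures: synthetic EF tables and one shared recovery screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import caaxscreen as cs
from caaxscreen.enrichment import EFTable
from caaxscreen.motifs import enumerate_cxxx


def make_ef_table(ef_values, metadata=None) -> EFTable:
    """EFTable over the full space from a length-8000 EF vector."""
    ef = np.asarray(ef_values, dtype=float)
    assert ef.shape == (8000,)
    df = pd.DataFrame({
        "motif": enumerate_cxxx(),
        "freq25": np.full(8000, 1 / 8000),
        "freq37": np.full(8000, 1 / 8000),
        "ef": ef,
    })
    return EFTable(df, metadata=metadata or {"scale": "synthetic"})


@pytest.fixture
def constant_ef_table():
    return make_ef_table(np.full(8000, 2.5))


@pytest.fixture
def random_ef_table():
    rng = np.random.default_rng(1234)
    return make_ef_table(rng.lognormal(0.0, 0.5, 8000))


@pytest.fixture(scope="session")
def recovery_screen():
    """One simulated screen at default (selective) settings, shared across
    tests that check ground-truth recovery."""
    cfg = cs.SimulationConfig(seed=1)
    screen = cs.run_screen(cfg)
    table = cs.compute_ef(cs.pool_replicates(screen.replicates_25),
                          cs.pool_replicates(screen.replicates_37))
    return screen, table
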