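"""Shared fixtures.

Expensive artifacts (a full pipeline run on one simulated dataset) are
session-scoped so property tests can share them.
"""

import numpy as np
import pytest

from priorityrank import (
    EffectsTable,
    draw_architecture,
    draw_dataset,
    estimate,
)


def child_seeds(master, n):
    """Independent child seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] >> 1) for c in ss.spawn(n)]


@pytest.fixture(scope="session")
def sim2000():
    """One simulated dataset: 2000 variables, normal family, half null."""
    arch = draw_architecture(11, family="normal")
    return draw_dataset(arch, n=2000, seed=12)


@pytest.fixture(scope="session")
def effects2000(sim2000):
    return EffectsTable.from_frame(sim2000.to_frame())


@pytest.fixture(scope="session")
def result2000(effects2000):
    """Full priorityFDR pipeline output on the shared dataset."""
    return estimate(effects2000, seed=13)
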