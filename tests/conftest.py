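"""Shared fixtures: seeded synthetic runs reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cytoflux.events import EventTable
from cytoflux.panel import PD_CHANNELS, default_panel
from cytoflux.simulate import DriftSpec, default_config, simulate_run


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def mixed_run():
    """Mixed-culture LPS run with doublets, beads and linear drift."""
    config = default_config(
        n_events=1000,
        seed=3,
        doublet_rate=0.05,
        bead_fraction=1 / 21,
        drift=DriftSpec("linear", 0.5),
    )
    table, truth = simulate_run(config, "microglia+astrocyte", "LPS", 1)
    return config, table, truth


@pytest.fixture(scope="session")
def microglia_run():
    """Microglia-only LPS run (clean: no doublets, beads or drift)."""
    config = default_config(n_events=1000, seed=7)
    table, truth = simulate_run(config, "microglia", "LPS", 1)
    return config, table, truth


@pytest.fixture(scope="session")
def drift_run():
    """Run with 50% linear sensitivity decay and a 1:20 bead spike."""
    config = default_config(
        n_events=2500,
        seed=11,
        bead_fraction=1 / 21,
        drift=DriftSpec("linear", 0.5),
        timepoints=(0, 2, 24, 48),
    )
    table, truth = simulate_run(config, "microglia", "LPS", 1)
    return config, table, truth


def make_pd_table(rescaled: np.ndarray, raw: np.ndarray) -> EventTable:
    """Minimal table with raw Pd channels and injected rescaled values."""
    rescaled = np.atleast_2d(np.asarray(rescaled, dtype=float))
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    data = pd.DataFrame(raw, columns=list(PD_CHANNELS))
    roles = {ch: "palladium" for ch in PD_CHANNELS}
    table = EventTable(data, roles)
    for j, ch in enumerate(PD_CHANNELS):
        table.annotations[f"pdscaled_{ch}"] = rescaled[:, j]
    return table
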