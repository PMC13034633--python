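import numpy as np
import pandas as pd
import pytest

from vitacyt import (
    CohortSpec,
    EventTable,
    GateConfig,
    simulate_cohort,
    simulate_stained_well,
)


@pytest.fixture(scope="session")
def gate_config() -> GateConfig:
    return GateConfig()


@pytest.fixture(scope="session")
def control_well() -> EventTable:
    """Non-Eub338-probe control run with ample SytoBC+ events."""
    return simulate_stained_well(
        1e9, 0.999, 10, acquisition_fraction=0.005, seed=501, control_probe=True
    )


@pytest.fixture(scope="session")
def mixed_well() -> EventTable:
    """Stained well at 68% viable fraction, ~10^4 cells."""
    return simulate_stained_well(1e9, 0.68, 10, acquisition_fraction=0.01, seed=6)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(CohortSpec(n_subjects=90, seed=11))


def labelled_well(n_beads=850, n_live=0, n_dead=0, seed=0) -> EventTable:
    """Small well assembled from exact truth-label counts (no Poisson)."""
    from vitacyt.simulate import DEFAULT_NOISE, _make_events

    rng = np.random.default_rng(seed)
    return _make_events(rng, n_beads, n_live, n_dead, 0, DEFAULT_NOISE)
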