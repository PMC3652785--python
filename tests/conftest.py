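"""Shared fixtures.  The expensive reference simulations are session-scoped
and reused by the unit, property and acceptance tests."""

import numpy as np
import pytest

from gnrhsync.cli_io import child_seed
from gnrhsync.model_core import cell_preset, network_preset
from gnrhsync.simulate import (
    HeterogeneitySpec,
    default_initial_condition,
    sample_heterogeneity,
    simulate_cell,
    simulate_network,
)

MASTER_SEED = 20130410


@pytest.fixture(scope="session")
def table1_traj():
    """Reference single-cell run: 50 min burn-in discarded, 120 min kept."""
    return simulate_cell(cell_preset(), T=120.0, burn_in=50.0)


@pytest.fixture(scope="session")
def table2_run():
    """Full-synchronization network: N=50, kj ~ U[0.8, 1.2], 180 min."""
    kj, _ = sample_heterogeneity(
        HeterogeneitySpec(seed=child_seed(MASTER_SEED, "heterogeneity")), 50
    )
    p = network_preset("table2-full-sync", N=50, kj=kj)
    ic = default_initial_condition(p, seed=child_seed(MASTER_SEED, "phases"))
    traj = simulate_network(p, T=180.0, ic=ic)
    return traj, p


@pytest.fixture(scope="session")
def partial_recruitment_run():
    """Heterogeneous-sensitivity network (eta_j ~ U[0, 3]): N=50, 130 min,
    enough for two synchronization episodes."""
    spec = HeterogeneitySpec(
        eta_mode="uniform", eta_bounds=(0.0, 3.0),
        seed=child_seed(MASTER_SEED, "heterogeneity"),
    )
    kj, etaj = sample_heterogeneity(spec, 50)
    p = network_preset("table2-full-sync", N=50, kj=kj, etaj=etaj)
    ic = default_initial_condition(p, seed=child_seed(MASTER_SEED, "phases"))
    traj = simulate_network(p, T=130.0, ic=ic)
    return traj, p
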