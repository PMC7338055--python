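import numpy as np
import pytest

from gturcsim import (
    EnergyParams,
    LatticeGeometry,
    LatticeState,
    SimConfig,
    baseline_params,
)


@pytest.fixture(scope="session")
def geometry():
    return LatticeGeometry()


@pytest.fixture(scope="session")
def baseline():
    return baseline_params()


@pytest.fixture
def full_layer_state(geometry):
    return LatticeState(np.ones(geometry.n_pf, dtype=np.int64))


def make_state(occupied, n_pf=13, conformation="open"):
    """LatticeState with height 1 on the given protofilaments (or a mapping
    pf -> height)."""
    h = np.zeros(n_pf, dtype=np.int64)
    if isinstance(occupied, dict):
        for pf, height in occupied.items():
            h[pf] = height
    else:
        for pf in occupied:
            h[pf] = 1
    return LatticeState(h, conformation=conformation)


@pytest.fixture(scope="session")
def baseline_series():
    """Shared kinetic Monte Carlo ensembles (baseline parameters,
    conformational barrier 10 kBT) reused by the acceptance checks.

    200 trajectories per concentration over the series used for the
    transition-state census, 120 over the outer concentrations of the
    sweep."""
    from gturcsim.pipeline import simulate_concentration_series

    cfg = SimConfig(mode="gturc", t_max=500.0, stop_after_nucleation=True)
    series = {}
    for conc, n_sims in [
        (2.5, 120), (5.0, 120), (7.0, 200), (10.5, 200), (14.0, 200),
        (21.0, 200), (28.0, 200), (42.0, 120), (50.0, 120),
    ]:
        (ens,) = simulate_concentration_series(
            baseline_params(), [conc], n_sims, master_seed=20_000 + int(conc * 10), config=cfg
        )
        series[conc] = ens
    return series
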