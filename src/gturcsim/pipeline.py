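"""End-to-end plumbing: simulation ensembles → nucleation curves → exponent.

This is the in-silico replica of the experimental protocol: run ensembles
over a concentration series, build p(t) from closure (or 50 nm) times with
censored runs kept in the denominator, extract the initial rate of each
curve, and regress ln(rate) on ln(C).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .engine import EnsembleResult, SimConfig, run_ensemble
from .kinetics import EventTable, ExponentFit, NucleationCurve, WindowRule, build_curve, fit_exponent_rates, initial_rate
from .lattice import EnergyParams

__all__ = [
    "ensemble_event_table",
    "ensemble_initial_rate",
    "simulate_concentration_series",
    "estimate_exponent_from_ensembles",
    "simulate_exponent",
]

#: default p(t) grid spacing (s); fine enough to resolve nucleation at the
#: top of the concentration range, where median closure times are seconds
DEFAULT_GRID_DT = 0.25


def ensemble_event_table(ensemble: EnsembleResult) -> EventTable:
    """Collapse an ensemble into the tabular form the kinetics module reads:
    finite nucleation times as events, t_max as the censor time, n_sims as
    the nucleator count N0."""
    times = ensemble.nucleation_times()
    return EventTable(
        concentration=ensemble.config.concentration,
        times=times[np.isfinite(times)],
        censor_time=ensemble.config.t_max,
        n0=ensemble.n_sims,
        condition=ensemble.config.mode,
    )


def ensemble_initial_rate(
    ensemble: EnsembleResult,
    grid_dt: float = DEFAULT_GRID_DT,
    window_rule: WindowRule = WindowRule(),
) -> Tuple[float, float]:
    """Initial rate of the ensemble's p(t) curve (per second)."""
    table = ensemble_event_table(ensemble)
    grid = np.arange(0.0, ensemble.config.t_max + grid_dt / 2, grid_dt)
    curve = build_curve(table, grid)
    return initial_rate(curve, window_rule, use_probability=True)


def simulate_concentration_series(
    params: EnergyParams,
    concentrations: Sequence[float],
    n_sims: int,
    master_seed: int,
    config: Optional[SimConfig] = None,
    engine: str = "numba",
) -> List[EnsembleResult]:
    """One ensemble per concentration, seeds split deterministically from
    the master seed."""
    config = config or SimConfig()
    seeds = np.random.SeedSequence(master_seed).generate_state(len(concentrations))
    out = []
    for conc, seed in zip(concentrations, seeds):
        out.append(
            run_ensemble(
                params,
                config.replace(concentration=float(conc)),
                n_sims=n_sims,
                master_seed=int(seed & 0x7FFFFFFF),
                engine=engine,
            )
        )
    return out


def estimate_exponent_from_ensembles(
    ensembles: Sequence[EnsembleResult],
    grid_dt: float = DEFAULT_GRID_DT,
    window_rule: WindowRule = WindowRule(),
    min_events: int = 1,
) -> ExponentFit:
    """Initial rates per concentration, then the log-log power-law fit.

    Concentrations where nothing nucleated are dropped and reported.
    ``min_events`` additionally excludes rate points backed by fewer
    nucleation events than that (a rate estimated from a handful of events
    is Poisson-noise dominated); excluded points appear in ``dropped``."""
    points = []
    for ens in ensembles:
        rate, _ = ensemble_initial_rate(ens, grid_dt, window_rule)
        n_events = int(np.isfinite(ens.nucleation_times()).sum())
        if n_events < min_events:
            rate = 0.0  # reported via the fit's dropped list
        points.append((ens.config.concentration, rate))
    return fit_exponent_rates(points, window_rule=window_rule.describe())


def simulate_exponent(
    params: EnergyParams,
    concentrations: Sequence[float],
    n_sims: int,
    master_seed: int,
    mode: str = "gturc",
    t_max: float = 500.0,
    grid_dt: float = DEFAULT_GRID_DT,
    engine: str = "numba",
) -> Tuple[ExponentFit, List[EnsembleResult]]:
    """Full in-silico critical-nucleus measurement for one parameter set."""
    config = SimConfig(mode=mode, t_max=t_max, stop_after_nucleation=True)
    ensembles = simulate_concentration_series(
        params, concentrations, n_sims, master_seed, config=config, engine=engine
    )
    fit = estimate_exponent_from_ensembles(ensembles, grid_dt=grid_dt)
    return fit, ensembles
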