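"""Event-driven stochastic simulation of MT nucleation from γ-TuRC.

The simulator follows the first-reaction method: at every step one
exponential waiting time is drawn per possible event (dimer association on
each protofilament, dissociation of each occupied dimer, γ-TuRC ring
closure) and the event with the shortest time is executed.  Dissociation of
a dimer removes everything stacked above it in the same protofilament.

Two interchangeable drivers exist:

* a pure-Python reference (`run_simulation` with ``engine="python"``) that
  materialises explicit :class:`Event` objects and is the ground truth for
  the event rules, and
* a numba-compiled direct-method kernel (``engine="numba"``, default for
  ensembles) that is distributionally equivalent and fast enough for the
  hundreds-of-trajectories ensembles the analysis needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .lattice import (
    CLOSED,
    OPEN,
    EnergyParams,
    LatticeGeometry,
    LatticeState,
    dimer_bond_energy,
    mt_length_nm,
    prospective_lateral_weight,
)

__all__ = [
    "SimConfig",
    "Event",
    "SimResult",
    "EnsembleResult",
    "AbsorbingStateError",
    "CensoredTrajectoryError",
    "event_rates",
    "next_event",
    "apply_event",
    "run_simulation",
    "run_ensemble",
    "growth_speed",
    "spawn_seeds",
]

#: conversion from μM to M
_UM_TO_M = 1e-6

ASSOCIATION = "association"
DISSOCIATION = "dissociation"
CLOSURE = "closure"


class AbsorbingStateError(RuntimeError):
    """Raised when no event has a positive rate (nothing can ever happen)."""


class CensoredTrajectoryError(ValueError):
    """Raised when a quantity requiring a nucleation event is asked of a
    trajectory that never nucleated."""


@dataclass(frozen=True)
class SimConfig:
    """Run conditions of one stochastic trajectory.

    Parameters
    ----------
    concentration :
        Free αβ-tubulin concentration in μM, held constant.
    t_max :
        Maximum simulated time (s).
    length_max :
        Stopping MT length (nm).
    mode :
        ``"gturc"`` starts from an open, empty γ-TuRC and records the ring
        closure time as the nucleation time; ``"seed"`` starts from a closed
        template with the γ-bond set equal to the αβ–αβ bond and records the
        time the MT first reaches ``seed_nucleation_length_nm``.
    seed_nucleation_length_nm :
        Length threshold defining nucleation in seed mode (nm).
    rng_seed :
        Seed of the trajectory's random stream.
    dissociation :
        ``"terminal"`` (default) restricts dissociation channels to the
        topmost dimer of each protofilament.  ``"all"`` gives every
        occupied dimer its own channel with cascade removal of everything
        above it; because a buried dimer's rate is evaluated from its own
        bonds only, interior cuts then trigger catastrophe-like avalanches
        that cap MT length at a few hundred dimers, which is incompatible
        with the sustained micrometre-scale growth and the linear
        growth-speed curve the energy parameters are calibrated to — the
        switch is kept for sensitivity analysis.
    stop_after_nucleation :
        Stop the trajectory as soon as the nucleation event is recorded
        (saves the post-nucleation growth phase when only nucleation times
        are needed).
    trace_dt :
        Sampling interval (s) of the stored length trace.  0 records every
        event (python engine only); ``None`` disables the trace.
    seed_length_reduction :
        Which length reduction triggers seed-mode nucleation: ``"mean"``
        (mean protofilament height x 8 nm) or ``"tallest"`` (tallest
        protofilament).
    max_height :
        Optional cap on protofilament height (testing only; ``None`` off).
    """

    concentration: float = 10.5
    t_max: float = 500.0
    length_max: float = 2000.0
    mode: str = "gturc"
    seed_nucleation_length_nm: float = 50.0
    rng_seed: int = 0
    dissociation: str = "terminal"
    stop_after_nucleation: bool = False
    seed_length_reduction: str = "mean"
    trace_dt: Optional[float] = None
    max_height: Optional[int] = None
    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.t_max <= 0 or self.length_max <= 0:
            raise ValueError("t_max and length_max must be > 0")
        if self.mode not in ("gturc", "seed"):
            raise ValueError(f"mode must be 'gturc' or 'seed', got {self.mode!r}")
        if self.dissociation not in ("all", "terminal"):
            raise ValueError("dissociation must be 'all' or 'terminal'")
        if self.seed_length_reduction not in ("mean", "tallest"):
            raise ValueError("seed_length_reduction must be 'mean' or 'tallest'")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Event:
    kind: str
    pf: Optional[int] = None
    layer: Optional[int] = None
    rate: float = 0.0
    waiting_time: Optional[float] = None


@dataclass
class SimResult:
    """One stochastic trajectory."""

    nucleation_time: Optional[float]
    t_end: float
    rng_seed: int
    mode: str
    trace: Optional[np.ndarray] = None  # columns: t, total dimers, length nm
    closure_snapshot: Optional[np.ndarray] = None
    closure_lateral_weight: Optional[float] = None
    final_heights: Optional[np.ndarray] = None
    n_events: int = 0

    @property
    def censored(self) -> bool:
        return self.nucleation_time is None


@dataclass
class EnsembleResult:
    """A collection of trajectories run under shared parameters."""

    results: List[SimResult]
    params: EnergyParams
    config: SimConfig
    master_seed: int

    @property
    def n_sims(self) -> int:
        return len(self.results)

    def nucleation_times(self) -> np.ndarray:
        """Per-trajectory nucleation times, ``inf`` for censored runs."""
        return np.array(
            [math.inf if r.censored else r.nucleation_time for r in self.results]
        )

    def fraction_nucleated(self) -> float:
        times = self.nucleation_times()
        return float(np.isfinite(times).mean())

    def p_curve(self, grid: Optional[np.ndarray] = None, dt: float = 1.0) -> Tuple[np.ndarray, np.ndarray]:
        """Cumulative nucleation probability p(t) on a time grid.

        Censored trajectories stay in the denominator (they carry an
        infinite nucleation time), so p(t) is the fraction of *all*
        trajectories nucleated by t.
        """
        if grid is None:
            grid = np.arange(0.0, self.config.t_max + dt / 2, dt)
        times = np.sort(self.nucleation_times())
        p = np.searchsorted(times, grid, side="right") / self.n_sims
        return grid, p

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rng_seed": [r.rng_seed for r in self.results],
                "nucleation_time_s": [
                    np.nan if r.censored else r.nucleation_time for r in self.results
                ],
                "censored": [r.censored for r in self.results],
            }
        )


def effective_params(params: EnergyParams, config: SimConfig) -> EnergyParams:
    """Parameters actually used by the run: seed mode replaces the γ–αβ
    longitudinal bond with the αβ–αβ one (all longitudinal bonds equal)."""
    if config.mode == "seed":
        return params.replace(dG_long_gamma=params.dG_long_ab)
    return params


def initial_state(config: SimConfig) -> LatticeState:
    conformation = CLOSED if config.mode == "seed" else OPEN
    return LatticeState.empty(config.geometry, conformation=conformation)


def event_rates(state: LatticeState, params: EnergyParams, config: SimConfig) -> List[Event]:
    """Enumerate every possible event with its rate (no waiting times yet).

    Association adds on top of each protofilament at rate k_on·C; every
    occupied dimer carries a dissociation channel at
    koff = k_on·exp(ΔGtot/kBT); an open ring carries one closure channel at
    k_conf·exp(−ΔGclose/kBT) with ΔGclose built from the prospective lateral
    weight n.
    """
    geometry = config.geometry
    conc_M = config.concentration * _UM_TO_M
    events: List[Event] = []
    k_assoc = params.k_on * conc_M
    for pf in range(geometry.n_pf):
        h = int(state.heights[pf])
        if config.max_height is not None and h >= config.max_height:
            continue
        events.append(Event(ASSOCIATION, pf=pf, layer=h + 1, rate=k_assoc))
    for pf in range(geometry.n_pf):
        h = int(state.heights[pf])
        layers = range(h, h + 1) if config.dissociation == "terminal" else range(1, h + 1)
        for layer in layers:
            if layer < 1:
                continue
            dg = dimer_bond_energy(state, pf, layer, params, geometry)
            events.append(Event(DISSOCIATION, pf=pf, layer=layer, rate=params.k_on * math.exp(dg)))
    if state.conformation == OPEN:
        n_lat = prospective_lateral_weight(state, geometry)
        rate = params.k_conf * math.exp(-params.closure_barrier(n_lat))
        events.append(Event(CLOSURE, rate=rate))
    return events


def next_event(events: Sequence[Event], rng: np.random.Generator) -> Tuple[Event, float]:
    """First-reaction selection: one exponential waiting time per event,
    the minimum wins."""
    best: Optional[Event] = None
    best_dt = math.inf
    for ev in events:
        if ev.rate <= 0.0:
            continue
        u = rng.random()
        while u == 0.0:  # guard against log(0)
            u = rng.random()
        dt = -math.log(u) / ev.rate
        ev.waiting_time = dt
        if dt < best_dt:
            best, best_dt = ev, dt
    if best is None:
        raise AbsorbingStateError("all event rates are zero")
    return best, best_dt


def apply_event(state: LatticeState, event: Event, dt: Optional[float] = None) -> LatticeState:
    """Execute one event in place and advance the clock.

    Association increments the stack; dissociation at layer L truncates the
    stack to L − 1 (the dimer and everything above leave together); closure
    flips the conformation, irreversibly.
    """
    if event.kind == ASSOCIATION:
        if event.layer != state.heights[event.pf] + 1:
            raise RuntimeError("association event inconsistent with state (not a stack top)")
        state.heights[event.pf] += 1
    elif event.kind == DISSOCIATION:
        if not (1 <= event.layer <= state.heights[event.pf]):
            raise RuntimeError("dissociation event targets an unoccupied site")
        state.heights[event.pf] = event.layer - 1
    elif event.kind == CLOSURE:
        if state.conformation != OPEN:
            raise RuntimeError("closure event on a non-open state")
        state.conformation = CLOSED
    else:
        raise RuntimeError(f"unknown event kind {event.kind!r}")
    if dt is None:
        dt = event.waiting_time
    if dt is not None:
        if dt < 0:
            raise RuntimeError("negative waiting time")
        state.t += dt
    return state


def _run_python(params: EnergyParams, config: SimConfig) -> SimResult:
    geometry = config.geometry
    p_eff = effective_params(params, config)
    state = initial_state(config)
    rng = np.random.default_rng(config.rng_seed)
    nucl_time: Optional[float] = None
    closure_snapshot = None
    closure_n = None
    trace: List[Tuple[float, int, float]] = []
    record = config.trace_dt is not None
    next_sample = 0.0
    n_events = 0

    def sample(upto: float) -> None:
        nonlocal next_sample
        if not record:
            return
        if config.trace_dt == 0:
            return
        while next_sample <= upto:
            trace.append((next_sample, state.total_dimers, mt_length_nm(state, geometry)))
            next_sample += config.trace_dt

    sample(0.0) if (record and config.trace_dt) else None
    while state.t < config.t_max:
        events = event_rates(state, p_eff, config)
        try:
            ev, dt = next_event(events, rng)
        except AbsorbingStateError:
            state.t = config.t_max
            break
        if state.t + dt >= config.t_max:
            if record and config.trace_dt:
                sample(config.t_max)
            state.t = config.t_max
            break
        if record and config.trace_dt:
            sample(state.t + dt)
        apply_event(state, ev, dt)
        n_events += 1
        if record and config.trace_dt == 0:
            trace.append((state.t, state.total_dimers, mt_length_nm(state, geometry)))
        if ev.kind == CLOSURE and config.mode == "gturc" and nucl_time is None:
            nucl_time = state.t
            closure_snapshot = state.heights.copy()
            closure_n = prospective_lateral_weight(state, geometry)
            if config.stop_after_nucleation:
                break
        if config.mode == "seed" and nucl_time is None:
            if config.seed_length_reduction == "tallest":
                reached_len = state.heights.max() * geometry.dimer_rise_nm
            else:
                reached_len = mt_length_nm(state, geometry)
            if reached_len >= config.seed_nucleation_length_nm:
                nucl_time = state.t
                if config.stop_after_nucleation:
                    break
        if mt_length_nm(state, geometry) >= config.length_max:
            break

    return SimResult(
        nucleation_time=nucl_time,
        t_end=state.t,
        rng_seed=config.rng_seed,
        mode=config.mode,
        trace=np.array(trace) if record else None,
        closure_snapshot=closure_snapshot,
        closure_lateral_weight=closure_n,
        final_heights=state.heights.copy(),
        n_events=n_events,
    )


def _run_numba(params: EnergyParams, config: SimConfig) -> SimResult:
    from . import _kernel

    geometry = config.geometry
    p_eff = effective_params(params, config)
    if config.trace_dt:
        trace_t = np.arange(0.0, config.t_max + config.trace_dt / 2, config.trace_dt)
    else:
        trace_t = np.empty(0)
    out = _kernel.run_kmc(
        n_pf=geometry.n_pf,
        half_seam=geometry.seam_half_overlap,
        rise=geometry.dimer_rise_nm,
        k_on=p_eff.k_on,
        dg_ab=p_eff.dG_long_ab,
        dg_lat=p_eff.dG_lat_ab,
        dg_gamma=p_eff.dG_long_gamma,
        dg_conf=p_eff.dG_conf,
        k_conf=p_eff.k_conf,
        literal_sign=(p_eff.closure_sign == "literal"),
        conc_M=config.concentration * _UM_TO_M,
        t_max=config.t_max,
        length_max=config.length_max,
        seed_mode=(config.mode == "seed"),
        nucl_length=config.seed_nucleation_length_nm,
        stop_after_nucl=config.stop_after_nucleation,
        terminal_only=(config.dissociation == "terminal"),
        tallest_criterion=(config.seed_length_reduction == "tallest"),
        max_height=(config.max_height or 0),
        seed=config.rng_seed,
        trace_t=trace_t,
    )
    nucl_time, t_end, closure_h, closure_n, n_events, trace_sum = out
    trace = None
    if config.trace_dt:
        keep = trace_sum >= 0
        length = trace_sum[keep] / geometry.n_pf * geometry.dimer_rise_nm
        trace = np.column_stack([trace_t[keep], trace_sum[keep], length])
    nucleated = math.isfinite(nucl_time)
    return SimResult(
        nucleation_time=nucl_time if nucleated else None,
        t_end=t_end,
        rng_seed=config.rng_seed,
        mode=config.mode,
        trace=trace,
        closure_snapshot=closure_h.copy() if (nucleated and config.mode == "gturc") else None,
        closure_lateral_weight=closure_n if (nucleated and config.mode == "gturc") else None,
        final_heights=None,
        n_events=int(n_events),
    )


def run_simulation(
    params: EnergyParams,
    config: SimConfig,
    engine: str = "python",
) -> SimResult:
    """Run one trajectory to t_max, the stopping length, or (optionally)
    the nucleation event.  Deterministic given ``config.rng_seed``."""
    if engine == "python":
        return _run_python(params, config)
    if engine == "numba":
        return _run_numba(params, config)
    raise ValueError(f"engine must be 'python' or 'numba', got {engine!r}")


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive *n* per-trajectory seeds from a master seed (SeedSequence
    stream splitting, folded into the positive int32 range)."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def run_ensemble(
    params: EnergyParams,
    config: SimConfig,
    n_sims: int,
    master_seed: int,
    engine: str = "numba",
) -> EnsembleResult:
    """Run ``n_sims`` independent trajectories with reproducibly derived
    per-trajectory seeds and assemble them into an :class:`EnsembleResult`."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    seeds = spawn_seeds(master_seed, n_sims)
    results = [
        run_simulation(params, config.replace(rng_seed=int(s)), engine=engine)
        for s in seeds
    ]
    return EnsembleResult(results=results, params=params, config=config, master_seed=master_seed)


def growth_speed(result: SimResult) -> float:
    """Polymerization speed (nm/s) as the least-squares slope of the length
    trace over the polymerizing stretch: the whole trace in seed mode, the
    post-nucleation part in gturc mode."""
    if result.trace is None or len(result.trace) < 2:
        raise ValueError("growth_speed needs a recorded trace (set trace_dt)")
    t = result.trace[:, 0]
    length = result.trace[:, 2]
    if result.mode == "gturc":
        if result.censored:
            raise CensoredTrajectoryError(
                "growth speed is undefined for a censored gturc trajectory"
            )
        mask = t >= result.nucleation_time
        t, length = t[mask], length[mask]
    if len(t) < 2 or np.ptp(t) == 0:
        raise ValueError("trace too short for a slope")
    slope = np.polyfit(t, length, 1)[0]
    return float(slope)
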