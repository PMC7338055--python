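"""Synthetic single-molecule TIRF nucleation data.

Generates event tables with exactly the statistical structure the kinetics
pipeline assumes, so estimators can be calibrated end to end without
experimental data:

* template regime — each of N0 surface-attached nucleators fires after an
  independent exponential waiting time with rate k·C^n, administratively
  censored at the movie length;
* spontaneous regime — Poisson counts at a fixed time τ with mean k·C^n·τ;
* seeded regime — exponential waiting times with rate k·C^(n−1)·(C − C*);
* growth regime — speeds v = a·(C − C*) plus Gaussian noise (no clipping:
  speeds below C* are negative).

Concentrations enter in μM and the rate constant k absorbs the units, so
the exponent — not k — is the quantity comparable across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .kinetics import EventTable

__all__ = [
    "GeneratorSpec",
    "gen_gturc_events",
    "gen_spontaneous_counts",
    "gen_seed_events",
    "gen_growth_speeds",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study design of a synthetic nucleation experiment.

    Defaults mirror a realistic single-molecule movie: 200 nucleators per
    field, the template-regime concentration series, a 10-minute movie,
    C* = 1.4 μM and τ = 450 s (7.5 min).
    """

    n0: int = 200
    concentrations: Tuple[float, ...] = (7.0, 10.5, 14.0, 17.5, 21.0)
    n_true: float = 3.9
    k: float = 1e-6
    censor_time: float = 600.0
    c_star: float = 1.4
    tau: float = 450.0
    delay: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")


def _censored_table(
    rng: np.random.Generator, rate: float, spec: GeneratorSpec, conc: float, condition: str
) -> EventTable:
    if rate > 0:
        waits = rng.exponential(1.0 / rate, size=spec.n0) + spec.delay
    else:
        waits = np.full(spec.n0, np.inf)
    observed = waits[waits <= spec.censor_time]
    return EventTable(
        concentration=conc,
        times=observed,
        censor_time=spec.censor_time,
        n0=spec.n0,
        condition=condition,
    )


def gen_gturc_events(spec: GeneratorSpec) -> List[EventTable]:
    """Template-regime tables: per-nucleator exponential waiting times with
    rate k·C^n, censored at the movie length.  One table per concentration;
    byte-identical under a fixed seed."""
    rng = np.random.default_rng(spec.rng_seed)
    return [
        _censored_table(rng, spec.k * c**spec.n_true, spec, c, "gturc")
        for c in spec.concentrations
    ]


def gen_spontaneous_counts(spec: GeneratorSpec) -> List[Tuple[float, int]]:
    """Spontaneous-regime counts at t = τ: Poisson with mean k·C^n·τ."""
    rng = np.random.default_rng(spec.rng_seed)
    return [
        (c, int(rng.poisson(spec.k * c**spec.n_true * spec.tau)))
        for c in spec.concentrations
    ]


def gen_seed_events(spec: GeneratorSpec) -> List[EventTable]:
    """Seeded-regime tables: per-seed exponential waiting times with rate
    k·C^(n−1)·(C − C*); every concentration must exceed C*."""
    for c in spec.concentrations:
        if c <= spec.c_star:
            raise ValueError(f"concentration {c} uM must exceed c_star = {spec.c_star} uM")
    rng = np.random.default_rng(spec.rng_seed)
    return [
        _censored_table(
            rng,
            spec.k * c ** (spec.n_true - 1.0) * (c - spec.c_star),
            spec,
            c,
            "seed",
        )
        for c in spec.concentrations
    ]


def gen_growth_speeds(
    a: float,
    c_star: float,
    noise_sd: float,
    concentrations: Sequence[float],
    reps: int = 1,
    seed: int = 0,
) -> List[Tuple[float, float]]:
    """Growth speeds v = a·(C − C*) + Gaussian noise, ``reps`` measurements
    per concentration.  Negative speeds below C* are kept as is."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    out: List[Tuple[float, float]] = []
    for c in concentrations:
        for _ in range(reps):
            out.append((float(c), float(a * (c - c_star) + rng.normal(0.0, noise_sd))))
    return out
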