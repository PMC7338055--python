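"""Statistical pipeline for critical-nucleus estimation from nucleation data.

A nucleation experiment (or simulation ensemble) yields, per tubulin
concentration C, a list of per-MT nucleation times with administrative
censoring at the movie length.  Under the cooperative-assembly model the
early-time nucleation rate scales as a power law in concentration,

    dN/dt|t→0 = k · N0 · C^n ,

so the exponent of a log-log regression of initial rates on concentration
estimates the number n of αβ-tubulin dimers in the rate-limiting transition
state (the critical nucleus).  Three regimes are covered:

* template (γ-TuRC) nucleation — initial rates of N(t) or p(t) vs ln C;
* spontaneous nucleation — counts at a fixed time τ vs ln C;
* seeded assembly near the polymerization threshold — initial rates of
  p(t) vs ln(C − C*), where C* is the critical concentration from the
  growth-speed line v = a·(C − C*).

Cumulative counts carry the Poisson field-to-field band N ± 2√N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EventTable",
    "NucleationCurve",
    "ExponentFit",
    "WindowRule",
    "build_curve",
    "initial_rate",
    "fit_exponent_rates",
    "fit_exponent_counts_at_tau",
    "fit_exponent_seeded",
    "normalize_rates",
    "growth_speed_fit",
    "fold_change",
]


@dataclass
class EventTable:
    """Per-MT nucleation times at one concentration, with censoring.

    ``times`` holds only observed events; nucleators that never fired by
    ``censor_time`` are implied by ``n0`` (total nucleators observed) when
    it is known.
    """

    concentration: float
    times: np.ndarray
    censor_time: float
    n0: Optional[int] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float))
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if self.times.size and (self.times <= 0).any():
            raise ValueError("nucleation times must be > 0")
        if self.times.size and self.times.max() > self.censor_time + 1e-9:
            raise ValueError("nucleation times must not exceed the censor time")
        if self.n0 is not None and self.n0 < self.times.size:
            raise ValueError("n0 cannot be smaller than the number of observed events")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "concentration_uM": self.concentration,
                "nucleation_time_s": self.times,
                "censor_time_s": self.censor_time,
                "n0": np.nan if self.n0 is None else self.n0,
            }
        )


@dataclass
class NucleationCurve:
    """Cumulative nucleation counts on a time grid with the Poisson band."""

    time: np.ndarray
    counts: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    n0: Optional[int] = None
    concentration: Optional[float] = None

    @property
    def probability(self) -> Optional[np.ndarray]:
        if self.n0 is None or self.n0 == 0:
            return None
        return self.counts / self.n0

    def value_at(self, t: float) -> float:
        """Count at time t (step interpolation)."""
        idx = np.searchsorted(self.time, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float(self.counts[idx])


@dataclass
class WindowRule:
    """Definition of the 'initial, linear region' of a nucleation curve:
    the earliest grid points up to where N(t) first exceeds ``fraction`` of
    its final value, with at least ``min_points`` points."""

    fraction: float = 0.2
    min_points: int = 5

    def describe(self) -> str:
        return f"initial window: up to {self.fraction:.0%} of final count, >= {self.min_points} points"


@dataclass
class ExponentFit:
    """Result of a log-log power-law regression."""

    n: float
    stderr: float
    intercept: float
    r_squared: float
    points: List[Tuple[float, float]]
    dropped: List[Tuple[float, float]] = field(default_factory=list)
    window_rule: Optional[str] = None
    c_star: Optional[float] = None

    def to_record(self) -> dict:
        return {
            "schema_version": 1,
            "exponent": self.n,
            "stderr": self.stderr,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "points": [list(p) for p in self.points],
            "dropped": [list(p) for p in self.dropped],
            "window_rule": self.window_rule,
            "c_star": self.c_star,
        }


def build_curve(table: EventTable, grid: np.ndarray) -> NucleationCurve:
    """Step-cumulative counts of the event table on *grid*, with the
    Poisson 95% band N ± 2√N (clipped below at zero)."""
    grid = np.asarray(grid, dtype=float)
    counts = np.searchsorted(table.times, grid, side="right").astype(float)
    half = 2.0 * np.sqrt(counts)
    return NucleationCurve(
        time=grid,
        counts=counts,
        band_lower=np.clip(counts - half, 0.0, None),
        band_upper=counts + half,
        n0=table.n0,
        concentration=table.concentration,
    )


def initial_rate(
    curve: NucleationCurve,
    window_rule: WindowRule = WindowRule(),
    use_probability: bool = False,
) -> Tuple[float, float]:
    """Least-squares slope of the initial region of the nucleation curve.

    Returns ``(rate, stderr)``.  With ``use_probability`` the slope is taken
    on p(t) = N(t)/N0 (requires n0).  A flat zero curve returns (0, 0).
    """
    y = curve.counts
    if use_probability:
        p = curve.probability
        if p is None:
            raise ValueError("probability rate requested but the curve has no n0")
        y = p
    final = y[-1]
    if final == 0:
        return 0.0, 0.0
    above = np.nonzero(y > window_rule.fraction * final)[0]
    end = int(above[0]) + 1 if above.size else len(y)
    end = max(end, window_rule.min_points)
    end = min(end, len(y))
    if end < 3:
        raise ValueError(
            f"too few grid points ({end}) inside the initial window ({window_rule.describe()})"
        )
    res = stats.linregress(curve.time[:end], y[:end])
    return float(res.slope), float(res.stderr)


def _loglog_fit(
    x: Sequence[float],
    y: Sequence[float],
    dropped: List[Tuple[float, float]],
    window_rule: Optional[str] = None,
    c_star: Optional[float] = None,
) -> ExponentFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError(
            f"need >= 2 positive points for a log-log fit, got {x.size} "
            f"(dropped: {dropped})"
        )
    res = stats.linregress(np.log(x), np.log(y))
    return ExponentFit(
        n=float(res.slope),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=list(zip(x.tolist(), y.tolist())),
        dropped=dropped,
        window_rule=window_rule,
        c_star=c_star,
    )


def _split_positive(points: Sequence[Tuple[float, float]]):
    pos = [(c, r) for c, r in points if r > 0 and c > 0]
    dropped = [(c, r) for c, r in points if not (r > 0 and c > 0)]
    cs = [c for c, _ in pos]
    if len(set(cs)) < 2:
        raise ValueError(
            f"need >= 2 distinct concentrations with positive values, got {sorted(set(cs))} "
            f"(dropped: {dropped})"
        )
    return pos, dropped


def fit_exponent_rates(
    points: Sequence[Tuple[float, float]], window_rule: Optional[str] = None
) -> ExponentFit:
    """Critical-nucleus exponent from initial rates: OLS of ln(rate) on
    ln(C).  Zero-rate concentrations cannot enter a log fit; they are
    excluded and reported in ``dropped``."""
    pos, dropped = _split_positive(points)
    return _loglog_fit([c for c, _ in pos], [r for _, r in pos], dropped, window_rule)


def fit_exponent_counts_at_tau(points: Sequence[Tuple[float, float]]) -> ExponentFit:
    """Spontaneous-assembly exponent: OLS of ln N(τ) on ln(C) at a fixed
    reference time τ."""
    pos, dropped = _split_positive(points)
    return _loglog_fit([c for c, _ in pos], [n for _, n in pos], dropped)


def fit_exponent_seeded(
    points: Sequence[Tuple[float, float]], c_star: float
) -> ExponentFit:
    """Seeded-assembly exponent: OLS of ln(dp/dt|t→0) on ln(C − C*).

    Every concentration must exceed the critical concentration C*.  With
    c_star = 0 this reduces exactly to :func:`fit_exponent_rates`."""
    for c, _ in points:
        if c <= c_star:
            raise ValueError(f"concentration {c} uM does not exceed C* = {c_star} uM")
    shifted = [(c - c_star, r) for c, r in points]
    pos, dropped = _split_positive(shifted)
    fit = _loglog_fit([x for x, _ in pos], [r for _, r in pos], dropped, c_star=c_star)
    # report dropped points on the original concentration scale
    fit.dropped = [(x + c_star, r) for x, r in fit.dropped]
    fit.points = [(x + c_star, r) for x, r in fit.points]
    return fit


def normalize_rates(
    points: Sequence[Tuple[float, float]], c_ref: float, rtol: float = 1e-6
) -> List[Tuple[float, float]]:
    """Divide every rate by the rate at the reference concentration — the
    normalisation that allows pooling replicates with different nucleator
    counts.  Exponent fits are invariant under it."""
    ref = [r for c, r in points if math.isclose(c, c_ref, rel_tol=rtol, abs_tol=1e-9)]
    if not ref:
        raise ValueError(
            f"no point at reference concentration {c_ref} uM; available: "
            f"{sorted(c for c, _ in points)}"
        )
    if ref[0] == 0:
        raise ValueError("reference rate is zero; cannot normalize")
    return [(c, r / ref[0]) for c, r in points]


def growth_speed_fit(points: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Fit the growth-speed line v = a·(C − C*).

    Returns ``(a, C*)`` where C* is the x-intercept (critical concentration
    for plus-end polymerization).  All-zero speeds leave C* undefined."""
    c = np.array([p[0] for p in points], dtype=float)
    v = np.array([p[1] for p in points], dtype=float)
    if np.unique(c).size < 2:
        raise ValueError("growth_speed_fit needs >= 2 distinct concentrations")
    res = stats.linregress(c, v)
    if res.slope == 0:
        raise ValueError("flat speed data: slope zero, C* undefined")
    c_star = -res.intercept / res.slope
    return float(res.slope), float(c_star)


def fold_change(
    a: NucleationCurve, b: NucleationCurve, t_ref: float
) -> Tuple[float, Tuple[float, float]]:
    """Ratio N_b(t_ref)/N_a(t_ref) with a propagated Poisson 95% interval.

    The relative variance of a Poisson count N is 1/N; the interval is
    ratio · (1 ± 2·√(1/N_a + 1/N_b)), clipped below at zero."""
    na = a.value_at(t_ref)
    nb = b.value_at(t_ref)
    if na == 0:
        raise ZeroDivisionError(
            f"denominator curve has zero counts at t = {t_ref} s; fold change undefined"
        )
    ratio = nb / na
    rel = 2.0 * math.sqrt(1.0 / na + (1.0 / nb if nb > 0 else 0.0))
    return ratio, (max(ratio * (1 - rel), 0.0), ratio * (1 + rel))
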