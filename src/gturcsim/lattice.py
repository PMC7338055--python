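"""Lattice geometry and bond energetics of a microtubule templated on γ-TuRC.

The microtubule (MT) wall is modelled as 13 protofilaments of αβ-tubulin
dimers stacked on top of a ring of 13 γ-tubulin sites (the γ-tubulin ring
complex, γ-TuRC).  Each protofilament is a contiguous stack described by a
single integer height; layer 0 is the permanent γ-tubulin site and layers
≥ 1 are αβ-dimers.  The B-lattice seam introduces a fractional axial offset
between the last and the first protofilament, so lateral contacts across the
seam are split into two half-strength overlaps.

All free energies are expressed in units of kBT (kBT ≡ 1); negative values
are favourable.  Concentrations cross the public interface in μM and are
converted to molar internally when rates are formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

__all__ = [
    "EnergyParams",
    "LatticeGeometry",
    "LatticeState",
    "OPEN",
    "CLOSED",
    "baseline_params",
    "xmap215_params",
    "xmap215_ablong_only_params",
    "lateral_contacts",
    "dimer_bond_energy",
    "prospective_lateral_weight",
    "mt_length_nm",
]

OPEN = "open"
CLOSED = "closed"


@dataclass(frozen=True)
class EnergyParams:
    """Kinetic and thermodynamic constants of the nucleation model.

    Parameters
    ----------
    k_on :
        Association rate constant per protofilament (M^-1 s^-1).
    dG_long_ab :
        Longitudinal αβ–αβ bond free energy (kBT, ≤ 0).
    dG_lat_ab :
        Lateral αβ–αβ bond free energy (kBT, ≤ 0).
    dG_long_gamma :
        Longitudinal γ–αβ bond free energy (kBT, ≤ 0).
    dG_conf :
        Thermodynamic penalty of the open→closed γ-TuRC conformational
        change (kBT, ≥ 0).
    k_conf :
        Arrhenius pre-factor of the closure rate (s^-1, ≥ 0).
    closure_sign :
        Convention for the net closure barrier.  ``"magnitude"`` (default)
        uses ΔGclose = dG_conf − n·|dG_lat_ab| so that prospective lateral
        bonds lower the barrier; ``"literal"`` uses
        ΔGclose = dG_conf − n·dG_lat_ab, kept only for sensitivity checks.
    """

    k_on: float = 1.3e6
    dG_long_ab: float = -7.2
    dG_lat_ab: float = -6.5
    dG_long_gamma: float = 1.1 * -7.2
    dG_conf: float = 10.0
    k_conf: float = 0.01
    closure_sign: str = "magnitude"

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValueError(f"k_on must be > 0, got {self.k_on}")
        if self.k_conf < 0:
            raise ValueError(f"k_conf must be >= 0, got {self.k_conf}")
        if self.dG_conf < 0:
            raise ValueError(f"dG_conf must be >= 0, got {self.dG_conf}")
        for name in ("dG_long_ab", "dG_lat_ab", "dG_long_gamma"):
            if getattr(self, name) > 0:
                raise ValueError(f"{name} must be <= 0 (favourable), got {getattr(self, name)}")
        if self.closure_sign not in ("magnitude", "literal"):
            raise ValueError(f"closure_sign must be 'magnitude' or 'literal', got {self.closure_sign!r}")

    def closure_barrier(self, n_lateral: float) -> float:
        """Net free-energy barrier ΔGclose of the open→closed transition
        when *n_lateral* lateral-bond weight would form on closure."""
        if self.closure_sign == "magnitude":
            return self.dG_conf - n_lateral * abs(self.dG_lat_ab)
        return self.dG_conf - n_lateral * self.dG_lat_ab

    def replace(self, **kwargs) -> "EnergyParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatticeGeometry:
    """MT lattice geometry: 13 protofilaments, 1.5-dimer seam pitch, 8 nm dimer rise."""

    n_pf: int = 13
    seam_offset_dimers: float = 1.5
    dimer_rise_nm: float = 8.0

    def __post_init__(self) -> None:
        if self.n_pf < 1:
            raise ValueError("n_pf must be >= 1")
        if (2 * self.seam_offset_dimers) != int(2 * self.seam_offset_dimers):
            raise ValueError("seam_offset_dimers must be a multiple of 0.5")
        if self.dimer_rise_nm <= 0:
            raise ValueError("dimer_rise_nm must be > 0")

    @property
    def seam_half_overlap(self) -> bool:
        """True when the seam offset has a half-dimer fractional part, so a
        seam dimer contacts two half-overlapping partners."""
        return (self.seam_offset_dimers % 1.0) == 0.5


@dataclass
class LatticeState:
    """Occupancy of the template lattice plus γ-TuRC conformation and clock.

    ``heights[p]`` is the number of αβ-dimers stacked on protofilament ``p``;
    stacks are contiguous by construction of the event rules (dimers add on
    top; a dissociating dimer takes everything above it along).
    """

    heights: np.ndarray
    conformation: str = OPEN
    t: float = 0.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.int64)
        if self.heights.ndim != 1:
            raise ValueError("heights must be one-dimensional")
        if (self.heights < 0).any():
            raise ValueError("heights must be non-negative")
        if self.conformation not in (OPEN, CLOSED):
            raise ValueError(f"conformation must be '{OPEN}' or '{CLOSED}'")

    @classmethod
    def empty(cls, geometry: LatticeGeometry = LatticeGeometry(), conformation: str = OPEN) -> "LatticeState":
        return cls(heights=np.zeros(geometry.n_pf, dtype=np.int64), conformation=conformation)

    @property
    def total_dimers(self) -> int:
        return int(self.heights.sum())

    def copy(self) -> "LatticeState":
        return LatticeState(self.heights.copy(), self.conformation, self.t)


def _check_site(state: LatticeState, pf: int, layer: int) -> None:
    n_pf = state.heights.shape[0]
    if not (0 <= pf < n_pf):
        raise IndexError(f"protofilament index {pf} out of range 0..{n_pf - 1}")
    if layer < 1:
        raise IndexError(f"layer must be >= 1 (layer 0 is the γ-tubulin site), got {layer}")
    if layer > state.heights[pf]:
        raise ValueError(f"site (pf={pf}, layer={layer}) is unoccupied (height {state.heights[pf]})")


def lateral_contacts(
    state: LatticeState,
    geometry: LatticeGeometry,
    pf: int,
    layer: int,
) -> List[Tuple[int, int, float]]:
    """Occupied lateral neighbours of the dimer at (pf, layer) with weights.

    Non-seam adjacency pairs same layer indices at weight 1.  Across the seam
    (between protofilament ``n_pf - 1`` and 0) a dimer at layer *i* on the
    last protofilament half-overlaps the dimers at layers *i* and *i + 1* on
    protofilament 0, each at weight 0.5 (and symmetrically from the other
    side).  Only αβ-dimer sites count: layer 0 never appears.

    Returns a list of ``(neighbour_pf, neighbour_layer, weight)``.
    """
    _check_site(state, pf, layer)
    n_pf = geometry.n_pf
    if n_pf == 1:
        return []
    h = state.heights
    last = n_pf - 1
    out: List[Tuple[int, int, float]] = []

    def non_seam(npf: int) -> None:
        if h[npf] >= layer:
            out.append((npf, layer, 1.0))

    def seam_partners(npf: int, layers: List[int], w: float) -> None:
        for lay in layers:
            if lay >= 1 and h[npf] >= lay:
                out.append((npf, lay, w))

    half = geometry.seam_half_overlap
    # left neighbour
    if pf == 0:
        if half:
            seam_partners(last, [layer - 1, layer], 0.5)
        else:
            non_seam(last)
    else:
        non_seam(pf - 1)
    # right neighbour
    if pf == last:
        if half:
            seam_partners(0, [layer, layer + 1], 0.5)
        else:
            non_seam(0)
    else:
        non_seam(pf + 1)
    return out


def dimer_bond_energy(
    state: LatticeState,
    pf: int,
    layer: int,
    params: EnergyParams,
    geometry: LatticeGeometry = LatticeGeometry(),
) -> float:
    """Total bond free energy ΔGtot (kBT) of the dimer at (pf, layer).

    ΔGtot is the longitudinal bond energy (γ–αβ for layer 1, αβ–αβ above)
    plus the lateral contact weight times the lateral bond energy.  In the
    open γ-TuRC conformation lateral bonds cannot form, at any layer, so the
    lateral sum is zero.
    """
    _check_site(state, pf, layer)
    e = params.dG_long_gamma if layer == 1 else params.dG_long_ab
    if state.conformation == CLOSED:
        w = sum(c[2] for c in lateral_contacts(state, geometry, pf, layer))
        e += w * params.dG_lat_ab
    return e


def prospective_lateral_weight(state: LatticeState, geometry: LatticeGeometry = LatticeGeometry()) -> float:
    """Total lateral contact weight that would exist were the ring closed.

    Each unordered occupied pair is counted once; seam half-overlaps count
    0.5.  This is the *n* entering the closure barrier ΔGclose.
    """
    h = state.heights
    n_pf = geometry.n_pf
    if n_pf == 1:
        return 0.0
    total = 0.0
    for p in range(n_pf - 1):
        total += min(h[p], h[p + 1])
    last = n_pf - 1
    if geometry.seam_half_overlap:
        total += 0.5 * min(h[last], h[0])
        total += 0.5 * min(h[last], max(h[0] - 1, 0))
    else:
        total += min(h[last], h[0])
    return float(total)


def mt_length_nm(state: LatticeState, geometry: LatticeGeometry = LatticeGeometry()) -> float:
    """MT length as mean protofilament height times the 8 nm dimer rise."""
    return float(state.heights.sum()) / geometry.n_pf * geometry.dimer_rise_nm


def baseline_params() -> EnergyParams:
    """The printed baseline parameter set (γ-TuRC-mediated nucleation)."""
    return EnergyParams()


def xmap215_params(base: EnergyParams | None = None) -> EnergyParams:
    """XMAP215 preset: both longitudinal bonds strengthened 1.2-fold.

    kon = 1.3e6 M^-1 s^-1 pf^-1, ΔGLong,αβ-αβ = −8.64 kBT,
    ΔGLat,αβ-αβ = −6.2 kBT, ΔGLong,γ-αβ = −9.5 kBT,
    k_conf = 0.01 s^-1, ΔGconf = 10 kBT.
    """
    base = base or baseline_params()
    return base.replace(dG_long_ab=-8.64, dG_lat_ab=-6.2, dG_long_gamma=-9.5)


def xmap215_ablong_only_params(base: EnergyParams | None = None) -> EnergyParams:
    """Negative-control variant: only the αβ–αβ longitudinal bond is
    strengthened 1.2-fold; the γ–αβ bond keeps its baseline value."""
    base = base or baseline_params()
    return base.replace(dG_long_ab=1.2 * base.dG_long_ab)
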