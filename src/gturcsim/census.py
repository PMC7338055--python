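"""Census of the γ-TuRC transition state.

In the model, the state of the lattice at the instant of ring closure *is*
the transition state of nucleation.  This module pools closure snapshots
across ensembles and summarises how many αβ-dimers were present, how much
lateral-bond weight they would form on closure, and how they were grouped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .engine import EnsembleResult, SimResult
from .lattice import LatticeGeometry, LatticeState, CLOSED, prospective_lateral_weight

__all__ = ["TransitionSnapshot", "CensusSummary", "snapshot_at_closure", "census", "group_pattern"]


def group_pattern(heights: np.ndarray) -> str:
    """Sorted sizes of maximal laterally contiguous layer-1 groups, e.g.
    ``"4"`` or ``"2+3"``.

    Grouping uses layer-1 occupancy and full-strength (non-seam) adjacency
    only, so the protofilament chain is linear: the half-overlaps across the
    seam never merge two groups.
    """
    occ = np.asarray(heights) >= 1
    sizes: List[int] = []
    run = 0
    for o in occ:
        if o:
            run += 1
        elif run:
            sizes.append(run)
            run = 0
    if run:
        sizes.append(run)
    if not sizes:
        return "0"
    return "+".join(str(s) for s in sorted(sizes))


@dataclass(frozen=True)
class TransitionSnapshot:
    """Lattice occupancy at the instant of ring closure."""

    heights: tuple
    total_dimers: int
    lateral_weight: float
    pattern: str

    @classmethod
    def from_heights(
        cls, heights: np.ndarray, geometry: LatticeGeometry = LatticeGeometry()
    ) -> "TransitionSnapshot":
        heights = np.asarray(heights, dtype=np.int64)
        state = LatticeState(heights.copy(), conformation=CLOSED)
        return cls(
            heights=tuple(int(x) for x in heights),
            total_dimers=int(heights.sum()),
            lateral_weight=prospective_lateral_weight(state, geometry),
            pattern=group_pattern(heights),
        )


@dataclass
class CensusSummary:
    """Pooled statistics over transition snapshots."""

    n_snapshots: int
    mean_total_dimers: float
    std_total_dimers: float
    histogram: pd.DataFrame  # columns: total_dimers, lateral_weight, probability
    modal_cell: Tuple[int, float]
    pattern_frequencies: Dict[str, float]

    def to_record(self) -> dict:
        return {
            "schema_version": 1,
            "n_snapshots": self.n_snapshots,
            "mean_total_dimers": self.mean_total_dimers,
            "std_total_dimers": self.std_total_dimers,
            "modal_total_dimers": self.modal_cell[0],
            "modal_lateral_weight": self.modal_cell[1],
            "pattern_frequencies": self.pattern_frequencies,
            "histogram": self.histogram.to_dict(orient="list"),
        }


def snapshot_at_closure(
    result: SimResult, geometry: LatticeGeometry = LatticeGeometry()
) -> TransitionSnapshot:
    """Transition snapshot of one nucleating gturc-mode trajectory."""
    if result.censored or result.closure_snapshot is None:
        raise ValueError("snapshot_at_closure requires a non-censored gturc trajectory")
    return TransitionSnapshot.from_heights(result.closure_snapshot, geometry)


def census(
    ensembles: Iterable[EnsembleResult] | Iterable[TransitionSnapshot],
) -> CensusSummary:
    """Pool closure snapshots across ensembles and summarise them.

    Accepts either :class:`EnsembleResult` objects (censored trajectories
    are skipped) or pre-built :class:`TransitionSnapshot` objects.
    Probabilities are normalised over the pooled snapshots; the modal
    (total dimers, lateral weight) cell breaks ties toward the smaller
    total, then the smaller weight.
    """
    snaps: List[TransitionSnapshot] = []
    for item in ensembles:
        if isinstance(item, TransitionSnapshot):
            snaps.append(item)
        else:
            geometry = item.config.geometry
            for r in item.results:
                if not r.censored and r.closure_snapshot is not None:
                    snaps.append(TransitionSnapshot.from_heights(r.closure_snapshot, geometry))
    if not snaps:
        raise ValueError("census requires at least one non-censored snapshot")

    totals = np.array([s.total_dimers for s in snaps])
    weights = np.array([s.lateral_weight for s in snaps])
    n = len(snaps)
    cells = Counter(zip(totals.tolist(), weights.tolist()))
    hist = pd.DataFrame(
        [(int(td), float(lw), c / n) for (td, lw), c in sorted(cells.items())],
        columns=["total_dimers", "lateral_weight", "probability"],
    )
    modal = min(cells.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))[0]
    patterns = Counter(s.pattern for s in snaps)
    return CensusSummary(
        n_snapshots=n,
        mean_total_dimers=float(totals.mean()),
        std_total_dimers=float(totals.std(ddof=1)) if n > 1 else 0.0,
        histogram=hist,
        modal_cell=(int(modal[0]), float(modal[1])),
        pattern_frequencies={k: v / n for k, v in sorted(patterns.items())},
    )
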