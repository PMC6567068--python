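"""Index <-> applied-potential mapping for concatenated CSWV traces.

A cyclic square-wave voltammogram is recorded as a cathodic sweep (potential
descending) immediately followed by an anodic sweep (ascending), and the two
current traces are concatenated into a single vector.  The instrument settings
used for the seawater library sweep between +1.0 V and -1.0 V vs. Ag/AgCl with
a 4 mV potential increment, giving 502 cathodic points followed by 500 anodic
points (1002 samples total).  The anodic branch restarts at -1.000 V, so its
index ``i`` maps to ``-1.000 + 0.004 * (i - 502)`` volts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PotentialGrid", "build_seawater_grid", "CATHODIC", "ANODIC"]

CATHODIC = "cathodic"
ANODIC = "anodic"


@dataclass(frozen=True)
class PotentialGrid:
    """Bijective map between sample index and applied potential.

    Parameters
    ----------
    n_points
        Total trace length (cathodic + anodic samples).
    boundary_index
        First index of the anodic branch.  May be 0 (purely anodic grid) or
        ``n_points`` (purely cathodic), which arise from truncation.
    cathodic_start
        Potential at index 0, in V vs. Ag/AgCl.  The cathodic branch steps
        *down* by ``step`` volts per sample.
    anodic_start
        Potential at ``boundary_index``.  The anodic branch steps *up*.
    step
        Potential increment magnitude in volts (> 0).
    """

    n_points: int = 1002
    boundary_index: int = 502
    cathodic_start: float = 1.000
    anodic_start: float = -1.000
    step: float = 0.004

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")
        if not (0 <= self.boundary_index <= self.n_points):
            raise ValueError("boundary_index outside 0..n_points")
        if self.step <= 0:
            raise ValueError("step must be positive")

    # -- branch geometry ---------------------------------------------------
    @property
    def n_cathodic(self) -> int:
        return self.boundary_index

    @property
    def n_anodic(self) -> int:
        return self.n_points - self.boundary_index

    def branch(self, index: int) -> str:
        self._check_index(index)
        return CATHODIC if index < self.boundary_index else ANODIC

    def _check_index(self, index: int) -> None:
        if not (0 <= index < self.n_points):
            raise IndexError(f"index {index} outside grid 0..{self.n_points - 1}")

    # -- index <-> potential ----------------------------------------------
    def potential(self, index: int) -> float:
        """Applied potential (V vs. Ag/AgCl) at a sample index."""
        self._check_index(index)
        if index < self.boundary_index:
            return round(self.cathodic_start - self.step * index, 9)
        return round(self.anodic_start + self.step * (index - self.boundary_index), 9)

    def potentials(self) -> np.ndarray:
        """Vector of potentials for all ``n_points`` samples."""
        cath = self.cathodic_start - self.step * np.arange(self.n_cathodic)
        anod = self.anodic_start + self.step * np.arange(self.n_anodic)
        return np.concatenate([cath, anod])

    def index_of(self, potential: float, branch: str) -> int:
        """Nearest grid index to ``potential`` on the given branch."""
        if branch == CATHODIC:
            idx = int(round((self.cathodic_start - potential) / self.step))
            lo, hi = 0, self.boundary_index - 1
        elif branch == ANODIC:
            idx = self.boundary_index + int(round((potential - self.anodic_start) / self.step))
            lo, hi = self.boundary_index, self.n_points - 1
        else:
            raise ValueError(f"unknown branch {branch!r}")
        if not (lo <= idx <= hi):
            raise ValueError(f"potential {potential} V outside the {branch} branch")
        return idx

    # -- slicing -----------------------------------------------------------
    def sliced(self, drop_head: int, drop_tail: int) -> "PotentialGrid":
        """Grid covering indices ``[drop_head, n_points - drop_tail)`` of this one."""
        if drop_head < 0 or drop_tail < 0:
            raise ValueError("drop counts must be nonnegative")
        new_n = self.n_points - drop_head - drop_tail
        if new_n < 2:
            raise ValueError("truncation leaves fewer than 2 points")
        new_boundary = min(max(self.boundary_index - drop_head, 0), new_n)
        anodic_skipped = max(0, drop_head - self.boundary_index)
        return PotentialGrid(
            n_points=new_n,
            boundary_index=new_boundary,
            cathodic_start=self.cathodic_start - self.step * drop_head,
            anodic_start=self.anodic_start + self.step * anodic_skipped,
            step=self.step,
        )


def build_seawater_grid() -> PotentialGrid:
    """Default 1002-point seawater grid (+1.000 V -> -1.004 V, -1.000 V -> +0.996 V)."""
    return PotentialGrid()
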