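"""Multi-metric trade-off surfaces: Goldberg Pareto fronts and the Pareto
Rank Ratio (PRR).

For a set of objective vectors (all oriented so larger is better), the
Goldberg ranking peels successive Pareto fronts: front 0 is the nondominated
set, which is removed, and the process repeats. Each node gets an optimal
rank R_o (front index when all objectives are maximised) and a suboptimal
rank R_s (front index when minimised). The PRR is

    PRR = 1                  if R_o = 0
    PRR = R_s / (R_o + R_s)  otherwise

giving a 0–1 optimality score per theoretical shape that is insensitive to
how densely performance space is occupied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .morphospace import TheoreticalGrid
from .performance import PerformanceSurface, _argmax_lex

__all__ = [
    "ParetoRanks",
    "dominates",
    "goldberg_fronts",
    "pareto_rank_ratio",
    "ParetoSurface",
    "build_pareto_surface",
]


@dataclass(frozen=True)
class ParetoRanks:
    """Goldberg front indices of one point: optimal (maximising) and
    suboptimal (minimising)."""

    R_o: int
    R_s: int

    def __post_init__(self) -> None:
        if self.R_o < 0 or self.R_s < 0:
            raise ParameterError("front indices must be >= 0")


def dominates(a, b) -> bool:
    """True iff a >= b componentwise with a > b somewhere (larger better)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ParameterError("objective vectors must be 1-D and equal length")
    return bool(np.all(a >= b) and np.any(a > b))


def goldberg_fronts(points) -> np.ndarray:
    """Front index of every point under iterative nondominated peeling.

    points: (n, k) array of objective vectors, larger better. Exact-tie
    vectors are mutually nondominating and share a front.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n = X.shape[0]
    if n < 1:
        raise ParameterError("need at least one point")
    fronts = np.full(n, -1, dtype=int)
    remaining = np.arange(n)
    level = 0
    while remaining.size:
        Y = X[remaining]
        # dom[i, j]: Y[i] dominates Y[j]
        ge = np.all(Y[:, None, :] >= Y[None, :, :], axis=2)
        gt = np.any(Y[:, None, :] > Y[None, :, :], axis=2)
        dominated = np.any(ge & gt, axis=0)
        if not np.any(~dominated):  # cannot happen with a finite strict order
            raise RuntimeError("no nondominated point found")
        fronts[remaining[~dominated]] = level
        remaining = remaining[dominated]
        level += 1
    return fronts


def pareto_rank_ratio(ranks: ParetoRanks) -> float:
    """PRR of one node; 1 whenever the node sits on the first optimal front."""
    if ranks.R_o == 0:
        return 1.0
    return ranks.R_s / (ranks.R_o + ranks.R_s)


@dataclass
class ParetoSurface:
    """PRR over a theoretical grid for a combination of metrics.

    ``prr`` in [0, 1] on valid nodes (NaN elsewhere); ``r_o``/``r_s`` hold
    the Goldberg front indices.
    """

    grid: TheoreticalGrid
    metric_names: list[str]
    directions: list[str]
    prr: np.ndarray
    r_o: np.ndarray
    r_s: np.ndarray
    peak_idx: tuple[int, int]

    @property
    def norm(self) -> np.ndarray:
        """PRR is already a 0-1 optimality value; alias for surface lookups."""
        return self.prr

    @property
    def peak_value(self) -> float:
        return float(self.prr[self.peak_idx])

    @property
    def peak_coords(self) -> tuple[float, float]:
        return self.grid.node_coords(*self.peak_idx)

    @property
    def name(self) -> str:
        return "+".join(self.metric_names)


def build_pareto_surface(
    grid: TheoreticalGrid, surfaces: list[PerformanceSurface]
) -> ParetoSurface:
    """PRR surface from >= 2 oriented performance surfaces on one grid.

    Objective vectors are the oriented normalised metric values of each valid
    node (fronts are computed over valid nodes only; impossible shapes take
    no part in functional analysis).
    """
    if len(surfaces) < 2:
        raise ParameterError("need at least two performance surfaces")
    for s in surfaces:
        if s.grid is not grid and (
            s.grid.nx != grid.nx
            or s.grid.ny != grid.ny
            or not np.allclose(s.grid.pc1_values, grid.pc1_values)
            or not np.allclose(s.grid.pc2_values, grid.pc2_values)
        ):
            raise ParameterError("surfaces were built on a different grid")
    mask = grid.valid
    obj = np.column_stack([s.norm[mask] for s in surfaces])
    r_o_flat = goldberg_fronts(obj)
    r_s_flat = goldberg_fronts(-obj)
    prr_flat = np.array(
        [
            pareto_rank_ratio(ParetoRanks(int(o), int(s)))
            for o, s in zip(r_o_flat, r_s_flat)
        ]
    )
    shape = (grid.nx, grid.ny)
    prr = np.full(shape, np.nan)
    r_o = np.full(shape, -1, dtype=int)
    r_s = np.full(shape, -1, dtype=int)
    prr[mask] = prr_flat
    r_o[mask] = r_o_flat
    r_s[mask] = r_s_flat
    peak = _argmax_lex(prr, mask)
    return ParetoSurface(
        grid=grid,
        metric_names=[s.metric_name for s in surfaces],
        directions=[s.direction for s in surfaces],
        prr=prr,
        r_o=r_o,
        r_s=r_s,
        peak_idx=peak,
    )
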