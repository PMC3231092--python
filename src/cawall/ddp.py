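"""Dual dynamic programming (DDP) extraction of two non-crossing curves.

Given an M x N cost grid (rows x columns), DDP finds two curves
``y1(x) <= y2(x)`` (one row per column each) that minimize

    sum_x [ cost(y1(x), x) + cost(y2(x), x) ]
        + sum_x [ alpha * |dw_x| + beta * (|j1| + |j2|) ]

subject to a per-column step bound ``|y(x) - y(x-1)| <= k`` for each curve
and a separation (thickness) band ``d_min <= y2(x) - y1(x) <= d_max`` at every
column.  ``dw_x`` is the change of the inter-curve distance between adjacent
columns, which for a joint step ``(j1, j2)`` equals ``|j2 - j1|``.

The optimum is exact: a full table of partial costs over states ``(y1, y2)``
is filled column by column and the optimal pair of curves is recovered by
backtracking through stored predecessor coordinates.

Coordinates are 0-based; rows increase downward (image convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DdpConfig",
    "DualTrace",
    "DdpTables",
    "penalty_matrix",
    "run_ddp",
    "run_single_dp",
]


@dataclass(frozen=True)
class DdpConfig:
    """Constraint set for the dual-curve optimization.

    Parameters
    ----------
    alpha : float
        Weight of the dual-line change smoothness term ``|j2 - j1|``.
    beta : float
        Weight of the single-line smoothness term ``|j1| + |j2|``.
    k : int
        Maximum per-column step of each curve, in pixels.
    d_min, d_max : int
        Minimum / maximum allowed separation ``y2 - y1`` in pixels.
        ``d_max=None`` resolves to ``round(0.9 * M)`` at run time (the
        fraction used for wall detection).
    orientation : str
        ``"minimize_cost"`` (default) treats the map as a cost and minimizes;
        ``"maximize_feature"`` flips the map to ``1 - map`` first, so bright
        feature ridges are sought.
    """

    alpha: float = 0.25
    beta: float = 0.15
    k: int = 1
    d_min: int = 4
    d_max: int | None = None
    orientation: str = "minimize_cost"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.d_min < 0:
            raise ValueError("d_min must be >= 0")
        if self.d_max is not None and self.d_max < self.d_min:
            raise ValueError("d_max must be >= d_min")
        if self.orientation not in ("minimize_cost", "maximize_feature"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")

    def resolve_d_max(self, n_rows: int) -> int:
        return int(round(0.9 * n_rows)) if self.d_max is None else int(self.d_max)


@dataclass
class DualTrace:
    """Two non-crossing row traces (one row index per column) and their cost."""

    y1: np.ndarray
    y2: np.ndarray
    total_cost: float


@dataclass
class DdpTables:
    """Partial-cost table J and predecessor coordinate tables C1, C2.

    ``J[x, y1, y2]`` is the optimal cost of any feasible dual path ending in
    state ``(y1, y2)`` at column ``x`` (``inf`` if infeasible).  ``C1``/``C2``
    hold the row coordinates of the optimal predecessor state at ``x - 1``.
    """

    J: np.ndarray
    C1: np.ndarray
    C2: np.ndarray


def penalty_matrix(alpha: float, beta: float, k: int) -> np.ndarray:
    """Smoothness penalty over joint steps, a (2k+1) x (2k+1) grid.

    Entry ``[j1 + k, j2 + k]`` equals ``alpha*|j2 - j1| + beta*(|j1| + |j2|)``.
    For k = 1 the two components are ``[[0,1,2],[1,0,1],[2,1,0]]`` and
    ``[[2,1,2],[1,0,1],[2,1,2]]``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    j = np.arange(-k, k + 1)
    j1 = j[:, None]
    j2 = j[None, :]
    return alpha * np.abs(j2 - j1) + beta * (np.abs(j1) + np.abs(j2))


def _offsets_in_preference_order(k: int) -> list[tuple[int, int]]:
    # Tie-break: (0,0) first, then smallest |j1|+|j2|, then lexicographic.
    offs = list(itertools.product(range(-k, k + 1), repeat=2))
    offs.sort(key=lambda o: (abs(o[0]) + abs(o[1]), o[0], o[1]))
    return offs


def _shift(table: np.ndarray, j1: int, j2: int) -> np.ndarray:
    """out[y1, y2] = table[y1 + j1, y2 + j2], inf where out of range."""
    m = table.shape[0]
    out = np.full_like(table, np.inf)
    a1, b1 = max(0, -j1), m - max(0, j1)
    a2, b2 = max(0, -j2), m - max(0, j2)
    if a1 < b1 and a2 < b2:
        out[a1:b1, a2:b2] = table[a1 + j1 : b1 + j1, a2 + j2 : b2 + j2]
    return out


def _values(cost_map) -> np.ndarray:
    return np.asarray(getattr(cost_map, "values", cost_map), dtype=float)


def run_ddp(cost_map, config: DdpConfig) -> tuple[DualTrace, DdpTables]:
    """Find the globally optimal pair of constrained curves on a cost grid.

    Parameters
    ----------
    cost_map : (M, N) array or FeatureMap
        Per-pixel cost, rows x columns.  Must be finite.
    config : DdpConfig

    Returns
    -------
    (DualTrace, DdpTables)
        The optimal trace (global minimum of the objective above) and the
        full cost/predecessor tables.
    """
    cost = _values(cost_map)
    if cost.ndim != 2:
        raise ValueError("cost_map must be 2-D (rows x columns)")
    m, n = cost.shape
    if n < 2:
        raise ValueError("cost_map must have at least 2 columns")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost_map contains non-finite values")
    if config.orientation == "maximize_feature":
        cost = 1.0 - cost

    k = config.k
    d_min = config.d_min
    d_max = config.resolve_d_max(m)
    if d_min > m - 1:
        raise ValueError(f"no feasible state: d_min={d_min} exceeds M-1={m - 1}")

    y1g, y2g = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    sep = y2g - y1g
    feasible = (sep >= d_min) & (sep <= d_max)
    if not feasible.any():
        raise ValueError("no feasible (y1, y2) state under the separation band")

    pen = penalty_matrix(config.alpha, config.beta, k)
    offsets = _offsets_in_preference_order(k)

    J = np.full((n, m, m), np.inf)
    C1 = np.zeros((n, m, m), dtype=np.int32)
    C2 = np.zeros((n, m, m), dtype=np.int32)

    col = cost[:, 0]
    J0 = col[:, None] + col[None, :]
    J0[~feasible] = np.inf
    J[0] = J0

    for x in range(1, n):
        prev = J[x - 1]
        best = np.full((m, m), np.inf)
        b1 = np.zeros((m, m), dtype=np.int32)
        b2 = np.zeros((m, m), dtype=np.int32)
        for j1, j2 in offsets:
            cand = _shift(prev, j1, j2) + pen[j1 + k, j2 + k]
            upd = cand < best  # strict: first offset in preference order wins ties
            if upd.any():
                best[upd] = cand[upd]
                b1[upd] = j1
                b2[upd] = j2
        col = cost[:, x]
        jx = best + col[:, None] + col[None, :]
        jx[~feasible] = np.inf
        J[x] = jx
        C1[x] = y1g + b1
        C2[x] = y2g + b2

    last = J[n - 1]
    total = last.min()
    if not np.isfinite(total):
        raise ValueError("no feasible dual path reaches the last column")
    # Smallest (y1, y2) lexicographically among equal-cost terminal states.
    end1, end2 = np.argwhere(last == total)[0]

    y1 = np.empty(n, dtype=int)
    y2 = np.empty(n, dtype=int)
    y1[-1], y2[-1] = end1, end2
    for x in range(n - 1, 0, -1):
        y1[x - 1] = C1[x, y1[x], y2[x]]
        y2[x - 1] = C2[x, y1[x], y2[x]]

    return DualTrace(y1=y1, y2=y2, total_cost=float(total)), DdpTables(J=J, C1=C1, C2=C2)


def run_single_dp(cost_map, config: DdpConfig) -> np.ndarray:
    """Extract a single optimal curve via the degenerate separation band [0, 1].

    Runs :func:`run_ddp` with ``d_min=0, d_max=1, k=1`` (the two curves are
    forced to coincide or stay within one row) and returns the upper curve,
    used as the outer-wall coordinate ``y_outer``.
    """
    cfg = replace(config, d_min=0, d_max=1, k=1)
    trace, _ = run_ddp(cost_map, cfg)
    return trace.y1
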