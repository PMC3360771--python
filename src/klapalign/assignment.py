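"""Exact k-cardinality linear assignment over squared inter-residue distances.

For a fixed rigid transform T the inner problem of the alignment model is:
choose exactly k one-to-one residue pairs (i, j) minimizing
``sum ||T(a_i) - b_j||^2``, with no sequence-order constraint. Its optimum
z* gives the transform's score ``F(T) = sqrt(z*/k)`` — the best attainable
RMSD at cardinality k.

The k-LAP is solved exactly by a standard reduction to a square linear
assignment problem of size (m + n - k): the m real rows are joined by
(n - k) dummy rows and the n real columns by (m - k) dummy columns;
real-dummy matches cost 0 and dummy-dummy matches carry a prohibitive
finite cost, which forces exactly k real-real matches in any optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .geometry import RigidTransform, apply_transform

__all__ = [
    "Alignment",
    "SubproblemResult",
    "build_cost_matrix",
    "solve_klap",
    "evaluate_F",
]


@dataclass(frozen=True)
class Alignment:
    """A one-to-one partial matching of residues of A to residues of B.

    ``pairs`` holds 1-based positional indices ``(i, j)`` along the parsed
    chains (not author residue numbers). Each i and each j appears at most
    once. ``k`` is the cardinality. An empty alignment is permitted as the
    result of extracting from an empty input.
    """

    pairs: tuple

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        seen_i = {i for i, _ in pairs}
        seen_j = {j for _, j in pairs}
        if len(seen_i) != len(pairs) or len(seen_j) != len(pairs):
            raise ValueError("alignment must be one-to-one: duplicate residue index")
        if pairs and (min(seen_i) < 1 or min(seen_j) < 1):
            raise ValueError("alignment indices are 1-based and must be >= 1")
        object.__setattr__(self, "pairs", pairs)

    @property
    def k(self) -> int:
        return len(self.pairs)

    def sorted_by_a(self) -> tuple:
        return tuple(sorted(self.pairs))

    def mapping(self) -> dict:
        """i -> j dictionary view of the matching."""
        return dict(self.pairs)


@dataclass(frozen=True)
class SubproblemResult:
    """Optimal assignment for one (transform, k): objective z* and F = sqrt(z*/k)."""

    alignment: Alignment
    objective: float  # sum of squared distances over chosen pairs, A^2
    rmsd: float  # F(T) = sqrt(objective / k), A


def build_cost_matrix(transform: RigidTransform, structure_a, structure_b) -> np.ndarray:
    """m x n matrix of squared distances between T(a_i) and b_j (Angstrom^2)."""
    coords_a = getattr(structure_a, "coords", structure_a)
    coords_b = getattr(structure_b, "coords", structure_b)
    moved = apply_transform(transform, coords_a)
    return cdist(moved, np.asarray(coords_b, dtype=float), "sqeuclidean")


def solve_klap(costs: np.ndarray, k: int) -> SubproblemResult:
    """Globally optimal cardinality-k matching of an m x n cost matrix.

    Returns the minimizing assignment (1-based pairs), its total cost, and
    the RMSD ``sqrt(cost / k)``. Ties between equally cheap assignments are
    broken arbitrarily by the underlying solver; the objective is unique.
    """
    costs = np.asarray(costs, dtype=float)
    if costs.ndim != 2:
        raise ValueError("cost matrix must be two-dimensional")
    m, n = costs.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"cardinality k={k} outside [1, {min(m, n)}]")
    if not np.all(np.isfinite(costs)) or np.any(costs < 0):
        raise ValueError("costs must be finite and nonnegative")

    if k == min(m, n):
        # rectangular LAP already returns exactly min(m, n) matches
        rows, cols = linear_sum_assignment(costs)
    else:
        size = m + n - k
        big = 1.0 + k * float(costs.max())
        padded = np.zeros((size, size))
        padded[:m, :n] = costs
        padded[m:, n:] = big  # forbid dummy-dummy matches
        prow, pcol = linear_sum_assignment(padded)
        real = (prow < m) & (pcol < n)
        rows, cols = prow[real], pcol[real]

    objective = float(costs[rows, cols].sum())
    pairs = tuple(zip((rows + 1).tolist(), (cols + 1).tolist()))
    return SubproblemResult(
        alignment=Alignment(pairs),
        objective=objective,
        rmsd=float(np.sqrt(objective / k)),
    )


def evaluate_F(transform: RigidTransform, structure_a, structure_b, k: int) -> SubproblemResult:
    """The master problem's objective callback: F(T) at cardinality k."""
    return solve_klap(build_cost_matrix(transform, structure_a, structure_b), k)
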