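"""Hitting times and the commute-time kinetic distance between microstates.

The hitting time ``h(i -> j)`` is the expected number of chain steps for a
walker started at ``i`` to first reach ``j``; the commute time
``D[i, j] = h(i -> j) + h(j -> i)`` is symmetric and serves as the kinetic
distance for the neighborhood-graph clustering.  Two microstates at small
commute distance sit in the same free-energy basin; a large commute distance
means they are far apart on the landscape or separated by a high barrier.

Two routes are provided: per-target linear solves of
``(I - T_minor) h = 1`` (simple, O(n^4) for the full matrix, used as an
independent cross-check) and the fundamental-matrix route
``Z = (I - T + 1 pi^T)^{-1}``, ``h(i -> j) = (Z[j, j] - Z[i, j]) / pi_j``
(production, O(n^3)).  Commute times are expressed in lag-time units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import minimum_spanning_tree

from .msm import MicrostateModel

__all__ = [
    "CommuteDistanceMatrix",
    "hitting_times_to",
    "commute_time_matrix",
    "scale_bounds",
]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class CommuteDistanceMatrix:
    """Symmetric commute-time distance matrix with its scale bounds.

    ``d_min`` is the smallest off-diagonal entry (below it every cluster is a
    singleton) and ``D_star`` the largest minimum-spanning-tree edge (at or
    above it the neighborhood graph over all states is connected), so useful
    scale parameters live in ``[d_min, D_star]``.
    """

    D: np.ndarray
    d_min: float
    D_star: float

    @property
    def n_states(self) -> int:
        return self.D.shape[0]


def hitting_times_to(T: np.ndarray, target: int) -> np.ndarray:
    """Expected first-passage times from every state to ``target``.

    Solves ``h_i = 1 + sum_k T[i, k] h_k`` for ``i != target`` with
    ``h_target = 0``.
    """
    n = T.shape[0]
    if not 0 <= target < n:
        raise IndexError(f"target {target} out of range for {n} states")
    others = np.delete(np.arange(n), target)
    A = np.eye(n - 1) - T[np.ix_(others, others)]
    try:
        h_others = linalg.solve(A, np.ones(n - 1))
    except linalg.LinAlgError as err:
        raise ValueError("singular hitting-time system: chain not irreducible") from err
    h = np.zeros(n)
    h[others] = h_others
    return h


def _commute_via_solves(T: np.ndarray) -> np.ndarray:
    n = T.shape[0]
    H = np.column_stack([hitting_times_to(T, j) for j in range(n)])
    return H + H.T


def commute_time_matrix(model: MicrostateModel, method: str = "fundamental") -> CommuteDistanceMatrix:
    """Commute-time distances between all pairs of microstates.

    ``method='fundamental'`` uses the fundamental matrix (one n x n inverse);
    ``method='solve'`` runs one linear solve per target state.  An
    ill-conditioned fundamental matrix triggers a warning and a fallback to
    the per-target solves.
    """
    T, pi = model.T, model.pi
    n = T.shape[0]
    if method == "solve":
        D = _commute_via_solves(T)
    elif method == "fundamental":
        A = np.eye(n) - T + np.outer(np.ones(n), pi)
        if np.linalg.cond(A) > _COND_LIMIT:
            warnings.warn("ill-conditioned fundamental matrix; falling back to per-target solves")
            D = _commute_via_solves(T)
        else:
            Z = linalg.inv(A)
            # h(i -> j) = (Z[j, j] - Z[i, j]) / pi_j
            H = (np.diag(Z)[None, :] - Z) / pi[None, :]
            D = H + H.T
    else:
        raise ValueError(f"unknown method {method!r}")
    D = 0.5 * (D + D.T)  # enforce exact symmetry against roundoff
    np.fill_diagonal(D, 0.0)
    d_min, d_star = scale_bounds(D)
    return CommuteDistanceMatrix(D=D, d_min=d_min, D_star=d_star)


def scale_bounds(D: np.ndarray) -> tuple[float, float]:
    """Bounds ``(d_min, D_star)`` for the scale parameter.

    ``d_min`` is the smallest off-diagonal distance; ``D_star`` is the
    largest edge of a minimum spanning tree of the complete graph weighted by
    ``D``, i.e. the smallest scale at which a single cluster remains.
    """
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two states for scale bounds")
    off = D[~np.eye(n, dtype=bool)]
    d_min = float(off.min())
    mst = minimum_spanning_tree(D)
    d_star = float(mst.data.max())
    return d_min, d_star
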