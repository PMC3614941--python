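"""Microstate Markov-model estimation from discrete trajectories.

The microstates are assumed to come from an upstream structural
discretization (e.g. k-center clustering of MD conformations); this module
consumes only sequences of integer microstate indices.  It estimates a
transition count matrix at a chosen lag, trims the chain to its largest
strongly connected component so that stationary probabilities and commute
times are finite, and derives the row-stochastic transition matrix ``T``,
the stationary distribution ``pi`` and the dimensionless free-energy proxy
``E_i = -ln(pi_i)`` (low ``E`` = deep basin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DiscreteTrajectories",
    "CountMatrix",
    "MicrostateModel",
    "count_transitions",
    "trim_to_ergodic",
    "transition_matrix",
    "stationary_distribution",
    "free_energies",
    "estimate_model",
]


@dataclass(frozen=True)
class DiscreteTrajectories:
    """A collection of integer microstate sequences.

    Parameters
    ----------
    trajectories
        One 1-D integer array per trajectory, 0-based microstate indices.
    n_states
        Number of microstates (max index + 1).  Inferred when omitted.
    """

    trajectories: tuple[np.ndarray, ...]
    n_states: int = 0

    def __post_init__(self) -> None:
        trajs = tuple(np.asarray(t, dtype=np.int64).ravel() for t in self.trajectories)
        if not trajs:
            raise ValueError("at least one trajectory is required")
        for t in trajs:
            if t.size and t.min() < 0:
                raise ValueError("microstate indices must be nonnegative")
        if not any(t.size >= 2 for t in trajs):
            raise ValueError("need at least one trajectory of length >= 2")
        inferred = int(max(t.max() for t in trajs if t.size)) + 1
        n = self.n_states or inferred
        if n < inferred:
            raise ValueError(f"n_states={n} smaller than max index {inferred - 1}")
        object.__setattr__(self, "trajectories", trajs)
        object.__setattr__(self, "n_states", n)

    @property
    def n_frames(self) -> int:
        return sum(t.size for t in self.trajectories)


@dataclass(frozen=True)
class CountMatrix:
    """Transition counts at a fixed lag plus per-state occupation counts."""

    counts: np.ndarray
    lag: int
    populations: np.ndarray

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class MicrostateModel:
    """Estimated microstate Markov model on the ergodic state set.

    ``state_map[k]`` gives the original microstate index of retained state
    ``k``; all matrices and vectors are indexed by retained states.
    """

    T: np.ndarray
    pi: np.ndarray
    E: np.ndarray
    populations: np.ndarray
    state_map: np.ndarray = field(default=None)  # type: ignore[assignment]
    lag: int = 1

    def __post_init__(self) -> None:
        if self.state_map is None:
            object.__setattr__(self, "state_map", np.arange(self.T.shape[0]))

    @property
    def n_states(self) -> int:
        return self.T.shape[0]


def count_transitions(
    trajs: DiscreteTrajectories, lag: int = 1, sliding: bool = True
) -> CountMatrix:
    """Count observed transitions ``i -> j`` at the given lag.

    With ``sliding=True`` (default) every ordered pair ``(t, t+lag)`` inside a
    trajectory contributes one count; with ``sliding=False`` pairs are taken
    at stride ``lag``.  ``populations`` counts every frame once regardless.
    """
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    n = trajs.n_states
    counts = np.zeros((n, n), dtype=np.int64)
    populations = np.zeros(n, dtype=np.int64)
    any_pairs = False
    for t in trajs.trajectories:
        populations += np.bincount(t, minlength=n)
        if t.size <= lag:
            continue
        any_pairs = True
        src = t[:-lag:1] if sliding else t[:-lag:lag]
        dst = t[lag::1] if sliding else t[lag::lag]
        np.add.at(counts, (src, dst), 1)
    if not any_pairs:
        raise ValueError(f"no transitions at this lag: all trajectories shorter than lag+1={lag + 1}")
    return CountMatrix(counts=counts, lag=lag, populations=populations)


def trim_to_ergodic(cm: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Restrict counts to the largest strongly connected component.

    States outside the largest SCC (directed graph with an edge ``i -> j``
    whenever ``counts[i, j] > 0``) have infinite hitting times to or from the
    rest of the chain, so they are removed before model estimation.  Returns
    the trimmed counts and ``state_map`` (retained original indices).
    """
    graph = csr_matrix((cm.counts > 0).astype(np.int8))
    n_comp, labels = connected_components(graph, directed=True, connection="strong")
    sizes = np.bincount(labels, minlength=n_comp)
    # break ties by total population so the dominant chain wins
    best = max(
        range(n_comp),
        key=lambda c: (sizes[c], int(cm.populations[labels == c].sum())),
    )
    keep = np.flatnonzero(labels == best)
    if keep.size < 2:
        raise ValueError("degenerate chain: largest strongly connected component has < 2 states")
    removed = cm.n_states - keep.size
    if removed:
        warnings.warn(f"trimmed {removed} of {cm.n_states} states outside the largest SCC")
    trimmed = CountMatrix(
        counts=cm.counts[np.ix_(keep, keep)],
        lag=cm.lag,
        populations=cm.populations[keep],
    )
    return trimmed, keep


def transition_matrix(cm: CountMatrix, symmetrize: bool = False, prior: float = 0.0) -> np.ndarray:
    """Row-normalize counts into a transition matrix.

    ``symmetrize`` averages the counts with their transpose first (a cheap
    reversible estimate); ``prior`` adds a uniform pseudocount.  Both are off
    by default so estimates are exactly reproducible from the counts.
    """
    C = cm.counts.astype(float)
    if symmetrize:
        C = 0.5 * (C + C.T)
    if prior:
        C = C + prior
    rowsums = C.sum(axis=1)
    if np.any(rowsums == 0):
        bad = np.flatnonzero(rowsums == 0)
        raise ValueError(f"zero row sum for states {bad.tolist()}; trim to the ergodic set first")
    return C / rowsums[:, None]


def stationary_distribution(T: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix.

    Solved as the null space of ``(T^T - I)`` with the normalization
    ``sum(pi) = 1`` appended, via least squares; the result is checked to be
    a valid fixed point.
    """
    n = T.shape[0]
    n_comp, _ = connected_components(csr_matrix(T > 0), directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError("transition matrix is not irreducible")
    A = np.vstack([T.T - np.eye(n), np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = linalg.lstsq(A, b)
    pi = np.maximum(pi, 0.0)
    s = pi.sum()
    if s <= 0:
        raise ValueError("failed to compute stationary distribution")
    pi = pi / s
    if np.max(np.abs(pi @ T - pi)) > 1e-8:
        raise ValueError("no unique stationary distribution: is the chain irreducible?")
    if np.any(pi <= tol):
        raise ValueError("stationary distribution has (near-)zero entries; chain not irreducible")
    return pi


def free_energies(pi: np.ndarray) -> np.ndarray:
    """Dimensionless free-energy proxy ``E_i = -ln(pi_i)``."""
    pi = np.asarray(pi, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("all stationary probabilities must be positive")
    return -np.log(pi)


def estimate_model(
    trajs: DiscreteTrajectories,
    lag: int = 1,
    sliding: bool = True,
    symmetrize: bool = False,
    prior: float = 0.0,
) -> MicrostateModel:
    """Full estimation pipeline: count, trim to the ergodic set, normalize."""
    cm = count_transitions(trajs, lag=lag, sliding=sliding)
    trimmed, state_map = trim_to_ergodic(cm)
    T = transition_matrix(trimmed, symmetrize=symmetrize, prior=prior)
    pi = stationary_distribution(T)
    return MicrostateModel(
        T=T,
        pi=pi,
        E=free_energies(pi),
        populations=trimmed.populations,
        state_map=state_map,
        lag=lag,
    )
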