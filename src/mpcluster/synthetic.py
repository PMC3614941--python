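"""Synthetic discrete trajectories with known metastable structure.

A Metropolis random walker on a landscape of inverted Gaussian wells stands
in for molecular dynamics: the downstream analysis consumes only discrete
trajectories, so any Markovian sampler with metastability exercises every
stage, and the planted wells provide ground truth for recovery tests.  Two
reference landscapes are provided:

* a 1-D three-basin landscape — two deep, well-separated basins A and B and
  a shallow basin C lying closer to A, with the A-C barrier lower than any
  barrier to B, so that at full density C naturally merges into A;
* a periodic 2-D torsion-like landscape with four prominent basins a-d of
  graded depth, a low barrier between a and b, and two small shallow basins
  e and f that are kinetically distant from the main wells — the signature
  of rare but kinetically distinct states.

Positions are discretized to a uniform grid per axis (row-major indexing)
to produce microstates.  These fixtures emulate the topology of real
free-energy landscapes, not their physics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .msm import DiscreteTrajectories

__all__ = [
    "Well",
    "LandscapeSpec",
    "SimulatedDataset",
    "make_three_basin_landscape",
    "make_alanine_like_landscape",
    "metropolis_trajectories",
    "discretize_grid",
    "basin_assignment",
]


@dataclass(frozen=True)
class Well:
    """Inverted generalized-Gaussian well.

    ``exponent=2`` is a plain Gaussian; larger even exponents flatten the
    bottom and steepen the walls, which concentrates the basin's population
    on a plateau (closer to the flat-bottomed basins separated by sharp
    ridges seen in torsion-angle free-energy maps).
    """

    center: tuple[float, ...]
    depth: float
    width: float
    exponent: float = 2.0


@dataclass(frozen=True)
class LandscapeSpec:
    """Potential = sum of inverted Gaussian wells on a flat background.

    The domain is the unit box [0, 1)^dimension; periodic landscapes wrap
    every axis (torsion-like).  ``temperature`` sets the Metropolis
    acceptance scale (well depths are in the same units, i.e. multiples of
    kT when temperature=1) and ``grid_bins`` the number of microstate bins
    per axis.
    """

    dimension: int
    periodic: bool
    wells: tuple[Well, ...]
    temperature: float
    grid_bins: int
    well_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("only 1-D and 2-D landscapes are supported")
        if self.grid_bins < 4:
            raise ValueError("need at least 4 grid bins per axis")
        for w in self.wells:
            if w.depth <= 0 or w.width <= 0:
                raise ValueError("well depths and widths must be positive")
        if not self.well_names:
            object.__setattr__(
                self, "well_names", tuple(f"w{k}" for k in range(len(self.wells)))
            )

    def potential(self, x: np.ndarray) -> np.ndarray:
        """Potential energy at positions ``x`` of shape (..., dimension)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        U = np.zeros(x.shape[0])
        for w in self.wells:
            delta = x - np.asarray(w.center)
            if self.periodic:
                delta = delta - np.round(delta)  # minimum image on the unit torus
            r2 = np.sum(delta**2, axis=-1)
            U -= w.depth * np.exp(-0.5 * (r2 / w.width**2) ** (w.exponent / 2.0))
        return U

    @property
    def n_microstates(self) -> int:
        return self.grid_bins**self.dimension


@dataclass(frozen=True)
class SimulatedDataset:
    """Discrete trajectories plus per-microstate ground-truth well labels."""

    trajectories: DiscreteTrajectories
    ground_truth: np.ndarray  # microstate -> well index (basin of attraction)
    spec: LandscapeSpec
    seed: int


def make_three_basin_landscape() -> LandscapeSpec:
    """1-D three-basin landscape: deep A and B, shallow C near A.

    A and C sit inside one broad shallow depression (the fourth, "shoulder"
    component), which puts the A-C saddle well below the flat background and
    hence far below the A-B barrier: C is connected to A at intermediate
    commute-time scales while B stays kinetically separate until near the
    full-connectivity scale.  Total depths: A about 5, B 4.8, C 3 (in units
    of kT at the default temperature).
    """
    return LandscapeSpec(
        dimension=1,
        periodic=False,
        wells=(
            Well(center=(0.18,), depth=3.2, width=0.050, exponent=6.0),  # A core
            Well(center=(0.80,), depth=4.8, width=0.060, exponent=6.0),  # B
            Well(center=(0.37,), depth=1.2, width=0.012, exponent=6.0),  # C core
            Well(center=(0.27,), depth=1.8, width=0.150, exponent=6.0),  # A+C depression
        ),
        temperature=1.0,
        grid_bins=50,
        well_names=("A", "B", "C", "shoulder"),
    )


def make_alanine_like_landscape() -> LandscapeSpec:
    """Periodic 2-D landscape with basins a-d plus small shallow e, f.

    Wells a and b share a low barrier (adjacent along one axis); e and f are
    narrow, shallow and placed far from the main wells so that they are
    rarely reached and hence kinetically distant.
    """
    return LandscapeSpec(
        dimension=2,
        periodic=True,
        wells=(
            Well(center=(0.25, 0.32), depth=6.0, width=0.12, exponent=6.0),  # a
            Well(center=(0.25, 0.62), depth=5.4, width=0.12, exponent=6.0),  # b (low barrier to a)
            Well(center=(0.72, 0.28), depth=4.8, width=0.10, exponent=6.0),  # c
            Well(center=(0.72, 0.68), depth=4.2, width=0.10, exponent=6.0),  # d
            Well(center=(0.025, 0.025), depth=3.6, width=0.028),  # e (small, shallow)
            Well(center=(0.525, 0.975), depth=3.6, width=0.028),  # f (small, shallow)
        ),
        temperature=1.0,
        grid_bins=20,
        well_names=("a", "b", "c", "d", "e", "f"),
    )


def metropolis_trajectories(
    spec: LandscapeSpec,
    n_traj: int,
    n_steps: int,
    step_size: float = 0.05,
    seed: int = 0,
) -> SimulatedDataset:
    """Sample discrete trajectories with a Metropolis random walker.

    All walkers start uniformly at random in the domain and move with
    Gaussian proposals of standard deviation ``step_size`` per axis,
    accepted with probability ``min(1, exp(-dU / temperature))``.  On a
    periodic landscape positions wrap; otherwise proposals leaving the unit
    box are rejected.  Every position (including the start) is recorded and
    discretized, so each trajectory has ``n_steps`` frames.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be at least 2")
    rng = np.random.default_rng(seed)
    d = spec.dimension
    x = rng.uniform(0.0, 1.0, size=(n_traj, d))
    U = spec.potential(x)
    states = np.empty((n_traj, n_steps), dtype=np.int64)
    states[:, 0] = discretize_grid(x, spec)
    accepted = 0
    for t in range(1, n_steps):
        prop = x + rng.normal(0.0, step_size, size=(n_traj, d))
        if spec.periodic:
            prop = np.mod(prop, 1.0)
            inside = np.ones(n_traj, dtype=bool)
        else:
            inside = np.all((prop >= 0.0) & (prop < 1.0), axis=1)
        U_prop = spec.potential(prop)
        accept = inside & (
            np.log(rng.uniform(size=n_traj)) < -(U_prop - U) / spec.temperature
        )
        x = np.where(accept[:, None], prop, x)
        U = np.where(accept, U_prop, U)
        accepted += int(accept.sum())
        states[:, t] = discretize_grid(x, spec)
    rate = accepted / (n_traj * (n_steps - 1))
    if rate < 1e-3:
        warnings.warn(f"Metropolis acceptance rate {rate:.2e}; step size may be too large")
    trajs = DiscreteTrajectories(
        trajectories=tuple(states[k] for k in range(n_traj)),
        n_states=spec.n_microstates,
    )
    return SimulatedDataset(
        trajectories=trajs,
        ground_truth=basin_assignment(spec),
        spec=spec,
        seed=seed,
    )


def discretize_grid(positions: np.ndarray, spec: LandscapeSpec) -> np.ndarray:
    """Map positions to row-major microstate indices on the uniform grid."""
    x = np.atleast_2d(np.asarray(positions, dtype=float))
    b = spec.grid_bins
    idx = np.floor(x * b).astype(np.int64)
    if spec.periodic:
        idx = np.mod(idx, b)
    else:
        if np.any((idx < 0) | (idx >= b)):
            warnings.warn("positions outside the unit box clamped to boundary bins")
            idx = np.clip(idx, 0, b - 1)
    flat = idx[:, 0]
    for axis in range(1, spec.dimension):
        flat = flat * b + idx[:, axis]
    return flat


def _bin_centers(spec: LandscapeSpec) -> np.ndarray:
    b = spec.grid_bins
    axis = (np.arange(b) + 0.5) / b
    if spec.dimension == 1:
        return axis[:, None]
    rows, cols = np.meshgrid(axis, axis, indexing="ij")
    return np.column_stack([rows.ravel(), cols.ravel()])


def basin_assignment(spec: LandscapeSpec) -> np.ndarray:
    """Ground-truth well label per microstate by discrete steepest descent.

    From each grid bin, repeatedly step to the lowest-potential neighbor
    (axis neighbors plus diagonals in 2-D; wrapping on periodic domains)
    until a local minimum is reached, then label by the nearest well center.
    """
    b = spec.grid_bins
    centers = _bin_centers(spec)
    U = spec.potential(centers)
    n = centers.shape[0]

    def neighbors(i: int) -> list[int]:
        if spec.dimension == 1:
            out = []
            for s in (-1, 1):
                k = i + s
                if spec.periodic:
                    out.append(k % b)
                elif 0 <= k < b:
                    out.append(k)
            return out
        r, c = divmod(i, b)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if spec.periodic:
                    rr, cc = rr % b, cc % b
                elif not (0 <= rr < b and 0 <= cc < b):
                    continue
                out.append(rr * b + cc)
        return out

    dest = np.arange(n)
    for i in range(n):
        cur = i
        for _ in range(n):
            nbrs = neighbors(cur)
            best = min(nbrs, key=lambda k: U[k])
            if U[best] >= U[cur]:
                break
            cur = best
        dest[i] = cur

    well_centers = np.array([w.center for w in spec.wells])
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        delta = centers[dest[i]] - well_centers
        if spec.periodic:
            delta = delta - np.round(delta)
        out[i] = int(np.argmin(np.sum(delta**2, axis=1)))
    return out
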