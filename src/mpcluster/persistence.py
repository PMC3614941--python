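"""Two-parameter (density x scale) persistence of neighborhood-graph clusters.

For a free-energy threshold ``theta_j`` the super level set ``L_j`` contains
every microstate with ``E_i <= theta_j`` (high stationary probability =
low free energy, so relaxing the threshold adds progressively rarer
microstates).  At each scale ``epsilon_l`` the members of ``L_j`` are
clustered as the connected components of the graph with an edge between two
microstates whenever their commute-time distance is at most ``epsilon_l`` —
exactly a single-linkage dendrogram cut at ``epsilon_l``.  Each component is
labeled by its member of minimum free energy, which lets the same cluster be
tracked across the whole (density index, scale index) grid: the set of grid
cells where a label still labels its own component is that cluster's
*persistence region*.  A region is always a staircase anchored at the
smallest scale — components only coarsen as ``epsilon`` or the level set
grows, so once a label has been absorbed by a deeper cluster it never
returns — and is therefore 4-connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import CommuteDistanceMatrix
from .msm import MicrostateModel

__all__ = [
    "ParameterGrid",
    "GridClustering",
    "MergeEvent",
    "PersistenceRegion",
    "build_grid",
    "superlevel_set",
    "neighborhood_clusters",
    "compute_grid",
    "persistence_regions",
    "max_persistences",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Density thresholds (free-energy units) and scale values (commute time).

    Indices are 0-based: density index ``j`` selects threshold ``thetas[j]``
    (larger ``j`` = more permissive = more microstates included) and scale
    index ``l`` selects ``epsilons[l]``.
    """

    thetas: np.ndarray
    epsilons: np.ndarray

    def __post_init__(self) -> None:
        thetas = np.asarray(self.thetas, dtype=float)
        epsilons = np.asarray(self.epsilons, dtype=float)
        if np.any(np.diff(thetas) <= 0) or np.any(np.diff(epsilons) <= 0):
            raise ValueError("thetas and epsilons must be strictly increasing")
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "epsilons", epsilons)

    @property
    def m(self) -> int:
        return self.thetas.size

    @property
    def q(self) -> int:
        return self.epsilons.size


@dataclass(frozen=True)
class GridClustering:
    """Labeled clusterings at every grid cell.

    ``labels[j, l, i]`` is the label (minimum-``E`` member, ties broken by
    lowest index) of the component containing microstate ``i`` at density
    index ``j`` and scale index ``l``, or -1 if ``i`` is not in the level
    set.  Component sizes are measured in conformations (sum of member
    populations).
    """

    grid: ParameterGrid
    labels: np.ndarray  # (m, q, n) int
    E: np.ndarray
    populations: np.ndarray

    @property
    def n_states(self) -> int:
        return self.labels.shape[2]

    def component_members(self, j: int, l: int, label: int) -> np.ndarray:
        """Microstates of the component labeled ``label`` at cell ``(j, l)``."""
        return np.flatnonzero(self.labels[j, l] == label)

    def cell_sizes(self, j: int, l: int) -> dict[int, int]:
        """Conformation count of every component at cell ``(j, l)``."""
        lab = self.labels[j, l]
        out: dict[int, int] = {}
        for c in np.unique(lab[lab >= 0]):
            out[int(c)] = int(self.populations[lab == c].sum())
        return out


@dataclass(frozen=True)
class MergeEvent:
    """One merge along a grid edge.

    ``axis`` is 'scale' for an ``l -> l+1`` step and 'density' for a
    ``j -> j+1`` step; ``kind`` is 'absorbs' when this cluster swallowed the
    listed labels, 'merged_by' when it was swallowed by a deeper one.
    """

    j: int
    l: int
    axis: str
    kind: str
    others: tuple[int, ...]


@dataclass(frozen=True)
class PersistenceRegion:
    """Grid cells on which one cluster label survives."""

    label: int
    cells: frozenset[tuple[int, int]]
    birth_level: int
    merge_events: tuple[MergeEvent, ...] = field(default=())

    def mask(self, m: int, q: int) -> np.ndarray:
        out = np.zeros((m, q), dtype=bool)
        for j, l in self.cells:
            out[j, l] = True
        return out


def build_grid(
    model: MicrostateModel,
    D: CommuteDistanceMatrix,
    m: int = 25,
    q: int = 25,
    strategy: str = "log",
) -> ParameterGrid:
    """Construct the (density, scale) parameter grid.

    Free-energy thresholds are always spaced as even quantiles of the
    observed ``E`` values (covering ``[min E, max E]``) except under
    ``strategy='linear'``.  The scale axis spans ``[d_min, D_star]`` and its
    spacing is set by ``strategy``: ``'log'`` (default) places the ``q``
    scales geometrically — commute times typically span several orders of
    magnitude (intra-basin diffusion times up to barrier-crossing times), so
    log spacing resolves cluster structure at every scale; ``'quantile'``
    uses even quantiles of the off-diagonal commute distances within the
    bounds; ``'linear'`` uses evenly spaced values.
    """
    if m < 2 or q < 2:
        raise ValueError("grid needs at least 2 values per axis")
    E = model.E
    n = D.n_states
    off = D.D[~np.eye(n, dtype=bool)]
    pool = off[(off >= D.d_min) & (off <= D.D_star)]
    if strategy == "log":
        thetas = np.quantile(E, np.linspace(0, 1, m))
        epsilons = np.geomspace(D.d_min, D.D_star, q)
    elif strategy == "quantile":
        thetas = np.quantile(E, np.linspace(0, 1, m))
        epsilons = np.quantile(pool, np.linspace(0, 1, q))
    elif strategy == "linear":
        thetas = np.linspace(E.min(), E.max(), m)
        epsilons = np.linspace(D.d_min, D.D_star, q)
    else:
        raise ValueError(f"unknown grid strategy {strategy!r}")
    thetas = _force_increasing(thetas, "density thresholds")
    epsilons = _force_increasing(epsilons, "scale parameters")
    return ParameterGrid(thetas=thetas, epsilons=epsilons)


def _force_increasing(values: np.ndarray, what: str) -> np.ndarray:
    """Nudge tied quantiles apart so the grid axes stay strictly increasing."""
    if np.ptp(values) == 0:
        warnings.warn(f"degenerate {what}: all values equal; using a single level")
        return values[:1]
    out = values.copy()
    eps = 1e-12 * max(1.0, float(np.abs(values).max()))
    for k in range(1, out.size):
        if out[k] <= out[k - 1]:
            out[k] = out[k - 1] + eps
    return out


def superlevel_set(E: np.ndarray, theta: float) -> np.ndarray:
    """Microstates at or below the free-energy threshold (sorted indices)."""
    members = np.flatnonzero(E <= theta)
    if members.size == 0:
        warnings.warn(f"empty level set at threshold {theta}")
    return members


def neighborhood_clusters(
    members: np.ndarray, D: np.ndarray, epsilon: float, E: np.ndarray
) -> dict[int, np.ndarray]:
    """Connected components of the epsilon-neighborhood graph on ``members``.

    Returns ``{label: member array}`` where the label is the component's
    minimum-``E`` microstate (ties broken by lowest index).  Equivalent to
    cutting a single-linkage dendrogram of the member set at ``epsilon``.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("member set must be nonempty")
    sub = D[np.ix_(members, members)]
    adj = csr_matrix((sub <= epsilon).astype(np.int8))
    _, comp = connected_components(adj, directed=False)
    out: dict[int, np.ndarray] = {}
    for c in np.unique(comp):
        group = members[comp == c]
        label = int(group[np.lexsort((group, E[group]))[0]])
        out[label] = group
    return out


def compute_grid(
    model: MicrostateModel, D: CommuteDistanceMatrix, grid: ParameterGrid
) -> GridClustering:
    """Cluster every super level set at every scale of the grid."""
    m, q, n = grid.m, grid.q, model.n_states
    labels = np.full((m, q, n), -1, dtype=np.int64)
    for j, theta in enumerate(grid.thetas):
        members = superlevel_set(model.E, theta)
        if members.size == 0:
            continue
        for l, eps in enumerate(grid.epsilons):
            for label, group in neighborhood_clusters(members, D.D, eps, model.E).items():
                labels[j, l, group] = label
    return GridClustering(grid=grid, labels=labels, E=model.E, populations=model.populations)


def persistence_regions(gc: GridClustering) -> list[PersistenceRegion]:
    """Extract one persistence region per label, with its merge events.

    A label's region is the set of cells where the component containing it is
    still labeled by it; regions are verified 4-connected (a violation would
    indicate an implementation bug, since components only coarsen along both
    grid axes).
    """
    m, q, n = gc.labels.shape
    labels = gc.labels
    is_label = np.zeros((m, q, n), dtype=bool)  # is_label[j, l, i]: i labels its component
    for i in range(n):
        is_label[:, :, i] = labels[:, :, i] == i
    regions: list[PersistenceRegion] = []
    thetas = gc.grid.thetas
    for i in range(n):
        mask = is_label[:, :, i]
        if not mask.any():
            continue
        in_set = np.flatnonzero(gc.E[i] <= thetas)
        birth = int(in_set[0])
        events: list[MergeEvent] = []
        for j, l in np.argwhere(mask):
            # scale step l -> l+1
            if l + 1 < q:
                if not mask[j, l + 1]:
                    events.append(MergeEvent(int(j), int(l), "scale", "merged_by", (int(labels[j, l + 1, i]),)))
                else:
                    absorbed = np.flatnonzero(
                        is_label[j, l] & ~is_label[j, l + 1] & (labels[j, l + 1] == i)
                    )
                    absorbed = absorbed[absorbed != i]
                    if absorbed.size:
                        events.append(MergeEvent(int(j), int(l), "scale", "absorbs", tuple(int(a) for a in absorbed)))
            # density step j -> j+1
            if j + 1 < m:
                if not mask[j + 1, l]:
                    events.append(MergeEvent(int(j), int(l), "density", "merged_by", (int(labels[j + 1, l, i]),)))
                else:
                    absorbed = np.flatnonzero(
                        is_label[j, l] & ~is_label[j + 1, l] & (labels[j + 1, l] == i)
                    )
                    absorbed = absorbed[absorbed != i]
                    if absorbed.size:
                        events.append(MergeEvent(int(j), int(l), "density", "absorbs", tuple(int(a) for a in absorbed)))
        _, n_comp = ndimage.label(mask)
        if n_comp != 1:
            raise AssertionError(
                f"persistence region of label {i} is not 4-connected ({n_comp} pieces); "
                "this indicates an implementation bug"
            )
        cells = frozenset((int(j), int(l)) for j, l in np.argwhere(mask))
        regions.append(
            PersistenceRegion(label=i, cells=cells, birth_level=birth, merge_events=tuple(events))
        )
    return regions


def _max_run(flags: np.ndarray) -> int:
    best = run = 0
    for f in flags:
        run = run + 1 if f else 0
        best = max(best, run)
    return best


def max_persistences(
    region: PersistenceRegion, gc: GridClustering
) -> tuple[int, int, int]:
    """Maximum persistence lengths (in grid indices) and maximum size.

    Returns ``(scale_persistence, density_persistence, max_size)``:
    the longest consecutive run of region cells along any density row, the
    longest run along any scale column, and the largest conformation count
    the labeled component attains anywhere in the region.
    """
    if not region.cells:
        raise ValueError("region is empty")
    m, q = gc.grid.m, gc.grid.q
    mask = region.mask(m, q)
    scale_p = max(_max_run(mask[j]) for j in range(m))
    density_p = max(_max_run(mask[:, l]) for l in range(q))
    max_size = 0
    for j, l in region.cells:
        size = int(gc.populations[gc.labels[j, l] == region.label].sum())
        max_size = max(max_size, size)
    return scale_p, density_p, max_size
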