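"""Cluster selection, partition construction and hierarchy extraction.

Persistent clusters are chosen by three principles: (i) long persistence in
the scale dimension (the cluster is kinetically disconnected from the rest),
(ii) long persistence in the density dimension *after the cluster appears*
(it sits in a deep basin — or, for late-born clusters, it survives most of
the levels available to it), and (iii) a significant number of
conformations.  Clusters passing (i) and (ii) but not (iii) are surfaced as
*rare-state candidates*: they may be genuinely small metastable states or
under-sampled regions, and that call is left to the user.

The selected candidates are then frozen into concrete *versions* (one grid
cell each, as large as possible without touching other candidates), padded
into a full partition of the microstates by minimum commute distance, and
arranged into a hierarchy by the density level at which their labels first
share a component at a reference scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .persistence import GridClustering, PersistenceRegion, max_persistences

__all__ = [
    "SelectionRules",
    "CandidateSet",
    "Partition",
    "HierarchyNode",
    "summarize",
    "select_candidates",
    "choose_versions",
    "full_partition",
    "hierarchy",
]


@dataclass(frozen=True)
class SelectionRules:
    """Thresholds for the three selection principles.

    Density persistence is always measured from a label's birth onward (the
    region cannot start earlier), so the density threshold asks the cluster
    to survive that many levels *after it appears* — a late-born cluster can
    still qualify, which is exactly the signature of a rare but kinetically
    distinct state, while noise states appearing at the last levels and
    dying immediately cannot.

    ``min_size`` separates fully selected clusters from rare-state
    candidates; ``min_rare_size`` separates rare-state candidates from
    outliers — a cluster below it is too thinly sampled to call a state at
    all, however persistent (few observed transitions inflate commute
    distances, so persistence alone cannot vouch for it).

    A rare-state candidate must also be kinetically distant from *all*
    other clusters, which shows as scale persistence reaching close to the
    full-connectivity scale ``D_star``: ``min_rare_scale_persistence``
    (default four fifths of the scale axis) encodes that.  A small cluster
    that merges at intermediate scales is just low-population structure
    inside a basin, not a distinct state.
    """

    min_scale_persistence: int
    min_density_persistence_after_birth: int
    min_size: int
    min_rare_size: int = 1
    min_rare_scale_persistence: int = 2

    @classmethod
    def defaults(cls, m: int, q: int, total_conformations: int) -> "SelectionRules":
        return cls(
            min_scale_persistence=max(2, math.ceil(q / 3)),
            min_density_persistence_after_birth=max(2, math.ceil(m / 3)),
            min_size=max(1, math.ceil(0.01 * total_conformations)),
            min_rare_size=max(1, math.ceil(0.001 * total_conformations)),
            min_rare_scale_persistence=max(2, math.ceil(0.8 * q)),
        )


@dataclass
class CandidateSet:
    """Selected cluster labels, rare-state candidates, and chosen versions."""

    selected: list[int]
    rare_state_candidates: list[int]
    versions: dict[int, tuple[int, int, np.ndarray]] = field(default_factory=dict)
    # label -> (j, l, member microstates)


@dataclass(frozen=True)
class Partition:
    """Microstate -> candidate-label assignment; -1 marks unassigned (core mode)."""

    assignment: np.ndarray
    mode: str


@dataclass(frozen=True)
class HierarchyNode:
    """Node of the cluster hierarchy; heights are density level indices."""

    label: int | None  # candidate label for leaves, None for internal nodes
    height: int
    children: tuple["HierarchyNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_newick(self, names: dict[int, str] | None = None) -> str:
        def render(node: HierarchyNode, parent_height: int | None) -> str:
            if node.is_leaf:
                name = names[node.label] if names else f"cluster_{node.label}"
            else:
                inner = ",".join(render(c, node.height) for c in node.children)
                name = f"({inner})"
            if parent_height is None:
                return name
            return f"{name}:{parent_height - node.height}"

        return render(self, None) + ";"

    def leaves(self) -> list["HierarchyNode"]:
        if self.is_leaf:
            return [self]
        out: list[HierarchyNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def summarize(regions: list[PersistenceRegion], gc: GridClustering) -> pd.DataFrame:
    """One row per nonempty region: persistences, max size, birth level."""
    rows = []
    for r in regions:
        sp, dp, size = max_persistences(r, gc)
        rows.append(
            {
                "label": r.label,
                "scale_persistence": sp,
                "density_persistence": dp,
                "max_size": size,
                "birth_level": r.birth_level,
            }
        )
    df = pd.DataFrame(rows, columns=["label", "scale_persistence", "density_persistence", "max_size", "birth_level"])
    return df.sort_values(
        ["scale_persistence", "density_persistence", "max_size"], ascending=False
    ).reset_index(drop=True)


def select_candidates(summary: pd.DataFrame, rules: SelectionRules) -> CandidateSet:
    """Apply the three selection principles to the diagram summary."""
    if summary.empty:
        raise ValueError("empty diagram summary")
    selected: list[int] = []
    rare: list[int] = []
    for row in summary.itertuples():
        if row.scale_persistence < rules.min_scale_persistence:
            continue
        if row.density_persistence < rules.min_density_persistence_after_birth:
            continue
        if row.max_size >= rules.min_size:
            selected.append(int(row.label))
        elif (
            row.max_size >= rules.min_rare_size
            and row.scale_persistence >= rules.min_rare_scale_persistence
        ):
            rare.append(int(row.label))
    if not selected:
        deepest = int(summary.loc[summary["birth_level"].idxmin(), "label"])
        warnings.warn("no label passed the selection rules; keeping only the deepest cluster")
        selected = [deepest]
    return CandidateSet(selected=selected, rare_state_candidates=rare)


def choose_versions(
    candidates: CandidateSet,
    regions: dict[int, PersistenceRegion],
    gc: GridClustering,
    include_rare: bool = True,
) -> CandidateSet:
    """Freeze one concrete version of each candidate cluster.

    Candidates are processed in descending free energy of their label, so
    shallow clusters claim their members before deep ones can swallow them.
    A candidate's version is the cell of its region whose component has the
    most conformations while containing neither another candidate's label
    microstate nor any member already claimed; if every cell conflicts, the
    birth cell (the smallest version) is used minus conflicting members.
    """
    labels = list(candidates.selected)
    if include_rare:
        labels += list(candidates.rare_state_candidates)
    order = sorted(labels, key=lambda c: -gc.E[c])
    label_set = set(labels)
    claimed = np.zeros(gc.n_states, dtype=bool)
    versions: dict[int, tuple[int, int, np.ndarray]] = {}
    for lab in order:
        region = regions[lab]
        other_labels = np.array(sorted(label_set - {lab}), dtype=int)
        cells = sorted(
            region.cells,
            key=lambda jl: -int(gc.populations[gc.labels[jl[0], jl[1]] == lab].sum()),
        )
        chosen = None
        for j, l in cells:
            members = gc.component_members(j, l, lab)
            if other_labels.size and np.isin(other_labels, members).any():
                continue
            if claimed[members].any():
                continue
            chosen = (j, l, members)
            break
        if chosen is None:
            j = region.birth_level
            ls = [l for (jj, l) in region.cells if jj == j]
            l = min(ls)
            members = gc.component_members(j, l, lab)
            members = members[~claimed[members] & ~np.isin(members, other_labels)]
            warnings.warn(f"candidate {lab}: every version conflicts; using trimmed birth cell")
            chosen = (j, l, members)
        claimed[chosen[2]] = True
        versions[lab] = chosen
    out = CandidateSet(
        selected=list(candidates.selected),
        rare_state_candidates=list(candidates.rare_state_candidates),
        versions=versions,
    )
    return out


def full_partition(
    candidates: CandidateSet,
    D: np.ndarray,
    E: np.ndarray,
    mode: str = "full",
) -> Partition:
    """Assign every microstate to a candidate cluster.

    Claimed microstates keep their version's label; in full mode every other
    microstate goes to the candidate minimizing the single-linkage commute
    distance ``min_{a in version} D[i, a]``, ties to the lower-free-energy
    label.  Core mode leaves them unassigned (-1).
    """
    if mode not in ("full", "core"):
        raise ValueError(f"unknown partition mode {mode!r}")
    n = D.shape[0]
    assignment = np.full(n, -1, dtype=np.int64)
    for lab, (_, _, members) in candidates.versions.items():
        if np.any(assignment[members] >= 0):
            raise ValueError("candidate versions overlap")
        assignment[members] = lab
    if mode == "full":
        free = np.flatnonzero(assignment < 0)
        if free.size:
            labs = sorted(candidates.versions, key=lambda c: E[c])  # low E first wins ties
            dist = np.stack(
                [D[np.ix_(free, candidates.versions[c][2])].min(axis=1) for c in labs]
            )
            choice = np.argmin(dist, axis=0)  # first (lowest-E) argmin on ties
            assignment[free] = np.asarray(labs)[choice]
    return Partition(assignment=assignment, mode=mode)


def hierarchy(
    candidates: CandidateSet,
    gc: GridClustering,
    regions: dict[int, PersistenceRegion],
    reference_scale_index: int | None = None,
) -> HierarchyNode:
    """Merge tree of the candidate clusters at one reference scale.

    Scanning density levels upward at the reference scale column, two
    candidates join at the first level where their label microstates share
    one component.  Leaves sit at their birth levels; a pair that never
    joins within the grid is attached to a virtual root one level above the
    top.  By default the reference column is the largest scale that still
    distinguishes at least two candidates at the most permissive density
    level — the most coarse-grained view that is not yet a single cluster,
    so the join levels spread over the density axis instead of collapsing
    at one extreme of the scale axis.
    """
    labels = sorted(candidates.versions) if candidates.versions else sorted(candidates.selected)
    if len(labels) < 2:
        raise ValueError("hierarchy needs at least two candidates")
    m, q = gc.grid.m, gc.grid.q
    if reference_scale_index is None:
        top = gc.labels[m - 1]
        l_ref = q // 2
        for l in range(q - 1, -1, -1):
            if len({int(top[l, lab]) for lab in labels}) >= 2:
                l_ref = l
                break
    else:
        l_ref = reference_scale_index
    nodes: dict[int, HierarchyNode] = {
        lab: HierarchyNode(label=lab, height=regions[lab].birth_level) for lab in labels
    }
    parent = {lab: lab for lab in labels}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(m):
        present = [lab for lab in labels if gc.labels[j, l_ref, lab] >= 0]
        groups: dict[int, list[int]] = {}
        for lab in present:
            groups.setdefault(int(gc.labels[j, l_ref, lab]), []).append(lab)
        for group in groups.values():
            roots = sorted({find(lab) for lab in group})
            if len(roots) > 1:
                merged = HierarchyNode(
                    label=None, height=j, children=tuple(nodes[r] for r in roots)
                )
                keep = roots[0]
                for r in roots[1:]:
                    parent[r] = keep
                nodes[keep] = merged
    roots = sorted({find(lab) for lab in labels})
    if len(roots) > 1:
        warnings.warn("candidates never merge at the reference scale; joining at a virtual root")
        return HierarchyNode(label=None, height=m, children=tuple(nodes[r] for r in roots))
    return nodes[roots[0]]
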