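"""Plain-text readers and writers for every pipeline artifact.

All artifacts are TSV/JSON/Newick so they can be inspected and diffed at the
typical problem sizes (up to ~1,000 microstates).  Microstate labels in
files are always the *original* input labels; the internal contiguous
indexing is recorded in ``state_map.tsv``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import CommuteDistanceMatrix
from .msm import DiscreteTrajectories, MicrostateModel
from .persistence import GridClustering, MergeEvent, ParameterGrid, PersistenceRegion
from .selection import CandidateSet, HierarchyNode, Partition

__all__ = [
    "read_dtrajs",
    "write_dtrajs",
    "write_model",
    "read_model",
    "write_distances",
    "read_distances",
    "write_grid",
    "read_grid",
    "write_summary",
    "write_candidates",
    "read_candidates",
    "write_partition",
    "write_tree",
]


def read_dtrajs(path: str | Path, fmt: str = "auto") -> tuple[DiscreteTrajectories, np.ndarray]:
    """Read discrete trajectories from a file or directory.

    Formats: ``'file'`` — each file is one trajectory of whitespace-separated
    integers; ``'line'`` — each line of one file is a trajectory; ``'auto'``
    picks ``'file'`` for directories and single-column files, ``'line'``
    otherwise.  Input labels need not be contiguous: they are remapped to
    0..k-1 and the original labels returned alongside.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trajectory input: {path}")
    raw: list[list[int]] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise ValueError(f"empty trajectory directory: {path}")
        for f in files:
            tokens = _parse_tokens(f)
            if not tokens:
                warnings.warn(f"skipping empty trajectory file {f}")
                continue
            raw.append(tokens)
    else:
        lines = path.read_text().splitlines()
        per_line = fmt == "line" or (
            fmt == "auto" and sum(len(ln.split()) > 1 for ln in lines) > 1
        )
        if per_line:
            for k, ln in enumerate(lines, start=1):
                if not ln.strip():
                    continue
                raw.append(_parse_line(ln, path, k))
        else:
            tokens = _parse_tokens(path)
            if not tokens:
                raise ValueError(f"empty trajectory file: {path}")
            raw.append(tokens)
    if not raw:
        raise ValueError(f"no trajectories found in {path}")
    labels = np.unique(np.concatenate([np.asarray(t) for t in raw]))
    remap = {int(v): i for i, v in enumerate(labels)}
    trajs = tuple(np.array([remap[v] for v in t], dtype=np.int64) for t in raw)
    return DiscreteTrajectories(trajectories=trajs, n_states=labels.size), labels


def _parse_tokens(path: Path) -> list[int]:
    out = []
    for k, ln in enumerate(path.read_text().splitlines(), start=1):
        out.extend(_parse_line(ln, path, k))
    return out


def _parse_line(line: str, path: Path, lineno: int) -> list[int]:
    out = []
    for tok in line.split():
        try:
            out.append(int(tok))
        except ValueError as err:
            raise ValueError(f"non-integer token {tok!r} at {path}:{lineno}") from err
    return out


def write_dtrajs(trajs: DiscreteTrajectories, path: Path, labels: np.ndarray | None = None) -> None:
    """Write trajectories one per line (original labels if provided)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for t in trajs.trajectories:
            vals = labels[t] if labels is not None else t
            fh.write(" ".join(str(int(v)) for v in vals) + "\n")


# --- model -----------------------------------------------------------------

def write_model(model: MicrostateModel, outdir: str | Path, labels: np.ndarray | None = None) -> Path:
    """Serialize a model as a directory of TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "T.tsv", model.T, delimiter="\t", fmt="%.17g")
    orig = labels[model.state_map] if labels is not None else model.state_map
    df = pd.DataFrame(
        {
            "retained_index": np.arange(model.n_states),
            "original_label": orig,
            "pi": model.pi,
            "E": model.E,
            "population": model.populations,
        }
    )
    df.to_csv(outdir / "state_map.tsv", sep="\t", index=False, float_format="%.17g")
    (outdir / "meta.json").write_text(json.dumps({"lag": model.lag, "n_states": model.n_states}))
    return outdir


def read_model(indir: str | Path) -> tuple[MicrostateModel, np.ndarray]:
    indir = Path(indir)
    T = np.loadtxt(indir / "T.tsv", delimiter="\t", ndmin=2)
    df = pd.read_csv(indir / "state_map.tsv", sep="\t")
    meta = json.loads((indir / "meta.json").read_text())
    model = MicrostateModel(
        T=T,
        pi=df["pi"].to_numpy(),
        E=df["E"].to_numpy(),
        populations=df["population"].to_numpy(),
        state_map=np.arange(T.shape[0]),
        lag=meta["lag"],
    )
    return model, df["original_label"].to_numpy()


# --- distances -------------------------------------------------------------

def write_distances(D: CommuteDistanceMatrix, path: str | Path, labels: np.ndarray | None = None) -> None:
    """Dense symmetric TSV with a header of original labels + JSON bounds sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = labels if labels is not None else np.arange(D.n_states)
    with open(path, "w") as fh:
        fh.write("\t".join(str(int(v)) for v in header) + "\n")
        np.savetxt(fh, D.D, delimiter="\t", fmt="%.17g")
    path.with_suffix(".bounds.json").write_text(
        json.dumps({"d_min": D.d_min, "D_star": D.D_star})
    )


def read_distances(path: str | Path) -> tuple[CommuteDistanceMatrix, np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        labels = np.array([int(v) for v in fh.readline().split()])
        D = np.loadtxt(fh, delimiter="\t", ndmin=2)
    bounds = json.loads(path.with_suffix(".bounds.json").read_text())
    return CommuteDistanceMatrix(D=D, d_min=bounds["d_min"], D_star=bounds["D_star"]), labels


# --- grid + regions --------------------------------------------------------

def write_grid(gc: GridClustering, regions: list[PersistenceRegion], path: str | Path) -> None:
    """JSON: grid parameters, sparse per-cell labelings, per-label regions."""
    cells = []
    for j in range(gc.grid.m):
        for l in range(gc.grid.q):
            lab = gc.labels[j, l]
            comps = {
                str(int(c)): np.flatnonzero(lab == c).tolist()
                for c in np.unique(lab[lab >= 0])
            }
            cells.append({"j": j, "l": l, "components": comps})
    payload = {
        "thetas": gc.grid.thetas.tolist(),
        "epsilons": gc.grid.epsilons.tolist(),
        "E": gc.E.tolist(),
        "populations": gc.populations.tolist(),
        "cells": cells,
        "regions": [
            {
                "label": r.label,
                "birth_level": r.birth_level,
                "cells": sorted(r.cells),
                "merge_events": [
                    {"j": e.j, "l": e.l, "axis": e.axis, "kind": e.kind, "others": list(e.others)}
                    for e in r.merge_events
                ],
            }
            for r in regions
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_grid(path: str | Path) -> tuple[GridClustering, list[PersistenceRegion]]:
    payload = json.loads(Path(path).read_text())
    grid = ParameterGrid(
        thetas=np.array(payload["thetas"]), epsilons=np.array(payload["epsilons"])
    )
    E = np.array(payload["E"])
    populations = np.array(payload["populations"])
    labels = np.full((grid.m, grid.q, E.size), -1, dtype=np.int64)
    for cell in payload["cells"]:
        for lab, members in cell["components"].items():
            labels[cell["j"], cell["l"], np.asarray(members, dtype=int)] = int(lab)
    gc = GridClustering(grid=grid, labels=labels, E=E, populations=populations)
    regions = [
        PersistenceRegion(
            label=r["label"],
            birth_level=r["birth_level"],
            cells=frozenset(map(tuple, r["cells"])),
            merge_events=tuple(
                MergeEvent(e["j"], e["l"], e["axis"], e["kind"], tuple(e["others"]))
                for e in r["merge_events"]
            ),
        )
        for r in payload["regions"]
    ]
    return gc, regions


# --- summary / candidates / partition / tree -------------------------------

def write_summary(summary: pd.DataFrame, path: str | Path, labels: np.ndarray | None = None) -> None:
    df = summary.copy()
    if labels is not None:
        df.insert(1, "original_label", labels[df["label"].to_numpy()])
    df.to_csv(path, sep="\t", index=False)


def write_candidates(candidates: CandidateSet, path: str | Path) -> None:
    payload = {
        "selected": candidates.selected,
        "rare_state_candidates": candidates.rare_state_candidates,
        "versions": {
            str(lab): {"j": j, "l": l, "members": members.tolist()}
            for lab, (j, l, members) in candidates.versions.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_candidates(path: str | Path) -> CandidateSet:
    payload = json.loads(Path(path).read_text())
    return CandidateSet(
        selected=payload["selected"],
        rare_state_candidates=payload["rare_state_candidates"],
        versions={
            int(lab): (v["j"], v["l"], np.asarray(v["members"], dtype=np.int64))
            for lab, v in payload["versions"].items()
        },
    )


def write_partition(partition: Partition, path: str | Path, labels: np.ndarray | None = None) -> None:
    """TSV microstate -> cluster, in original input labels."""
    n = partition.assignment.size
    orig = labels if labels is not None else np.arange(n)
    with open(path, "w") as fh:
        fh.write("microstate\tcluster\n")
        for i in range(n):
            a = partition.assignment[i]
            cluster = str(int(orig[a])) if a >= 0 else "unassigned"
            fh.write(f"{int(orig[i])}\t{cluster}\n")


def write_tree(tree: HierarchyNode, path: str | Path, labels: np.ndarray | None = None) -> None:
    names = None
    if labels is not None:
        names = {leaf.label: f"cluster_{int(labels[leaf.label])}" for leaf in tree.leaves()}
    Path(path).write_text(tree.to_newick(names) + "\n")
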