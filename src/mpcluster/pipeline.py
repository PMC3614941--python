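"""End-to-end pipeline: trajectories -> model -> distances -> persistence
-> selection -> partition -> hierarchy, with artifact output."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .distance import CommuteDistanceMatrix, commute_time_matrix
from .msm import DiscreteTrajectories, MicrostateModel, estimate_model
from .persistence import (
    GridClustering,
    PersistenceRegion,
    build_grid,
    compute_grid,
    persistence_regions,
)
from .selection import (
    CandidateSet,
    HierarchyNode,
    Partition,
    SelectionRules,
    choose_versions,
    full_partition,
    hierarchy,
    select_candidates,
)

logger = logging.getLogger("mpcluster")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_outputs"]


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one analysis run (JSON-serializable)."""

    lag: int = 1
    sliding: bool = True
    symmetrize: bool = False
    prior: float = 0.0
    m: int = 25
    q: int = 25
    strategy: str = "log"
    min_scale_persistence: int | None = None
    min_density_persistence: int | None = None
    min_size_fraction: float = 0.01
    rare_size_fraction: float = 0.001
    reference_scale_index: int | None = None
    mode: str = "full"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class PipelineResult:
    model: MicrostateModel
    D: CommuteDistanceMatrix
    gridclust: GridClustering
    regions: list[PersistenceRegion]
    summary: pd.DataFrame
    candidates: CandidateSet
    partition: Partition
    tree: HierarchyNode | None
    input_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    config: RunConfig = field(default_factory=RunConfig)

    @property
    def regions_by_label(self) -> dict[int, PersistenceRegion]:
        return {r.label: r for r in self.regions}

    def original_labels(self) -> np.ndarray:
        """Original input label of each retained microstate."""
        base = self.input_labels if self.input_labels is not None else np.arange(
            int(self.model.state_map.max()) + 1
        )
        return np.asarray(base)[self.model.state_map]


def run_pipeline(
    trajs: DiscreteTrajectories,
    config: RunConfig = RunConfig(),
    input_labels: np.ndarray | None = None,
) -> PipelineResult:
    """Run every stage of the multi-persistent clustering analysis."""

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("model estimation")
        model = estimate_model(
            trajs,
            lag=config.lag,
            sliding=config.sliding,
            symmetrize=config.symmetrize,
            prior=config.prior,
        )
        stage("commute-time distances")
        D = commute_time_matrix(model)
        stage("parameter grid + clusterings")
        grid = build_grid(model, D, m=config.m, q=config.q, strategy=config.strategy)
        gc = compute_grid(model, D, grid)
        stage("persistence regions")
        regions = persistence_regions(gc)
        from .selection import summarize

        summary = summarize(regions, gc)
        stage("candidate selection")
        total = int(model.populations.sum())
        defaults = SelectionRules.defaults(grid.m, grid.q, total)
        rules = SelectionRules(
            min_scale_persistence=config.min_scale_persistence
            if config.min_scale_persistence is not None
            else defaults.min_scale_persistence,
            min_density_persistence_after_birth=config.min_density_persistence
            if config.min_density_persistence is not None
            else defaults.min_density_persistence_after_birth,
            min_size=max(1, int(np.ceil(config.min_size_fraction * total))),
            min_rare_size=max(1, int(np.ceil(config.rare_size_fraction * total))),
            min_rare_scale_persistence=defaults.min_rare_scale_persistence,
        )
        candidates = select_candidates(summary, rules)
        stage("cluster versions")
        by_label = {r.label: r for r in regions}
        candidates = choose_versions(candidates, by_label, gc)
        stage("partition")
        partition = full_partition(candidates, D.D, model.E, mode=config.mode)
        stage("hierarchy")
        tree: HierarchyNode | None = None
        if len(candidates.versions) >= 2:
            tree = hierarchy(
                candidates, gc, by_label, reference_scale_index=config.reference_scale_index
            )
        else:
            warnings.warn("fewer than two candidates; skipping hierarchy")
    except Exception as err:
        raise RuntimeError(f"pipeline failed: {err}") from err
    return PipelineResult(
        model=model,
        D=D,
        gridclust=gc,
        regions=regions,
        summary=summary,
        candidates=candidates,
        partition=partition,
        tree=tree,
        input_labels=input_labels,
        config=config,
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> Path:
    """Write every artifact of a pipeline run to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    orig = result.original_labels()
    mio.write_model(result.model, outdir / "model", labels=result.input_labels)
    mio.write_distances(result.D, outdir / "D.tsv", labels=orig)
    mio.write_grid(result.gridclust, result.regions, outdir / "grid.json")
    mio.write_summary(result.summary, outdir / "summary.tsv", labels=orig)
    mio.write_candidates(result.candidates, outdir / "candidates.json")
    mio.write_partition(result.partition, outdir / "partition.tsv", labels=orig)
    if result.tree is not None:
        mio.write_tree(result.tree, outdir / "tree.nwk", labels=orig)
    (outdir / "run.log").write_text(result.config.to_json() + "\n")
    return outdir
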