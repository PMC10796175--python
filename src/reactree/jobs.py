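"""Replicate orchestration and output writing.

One job produces one NEXUS trees file and (for forward models) one TSV
trajectory-grid file covering all replicates; replicate ``r`` draws from a
deterministic RNG stream derived from ``(seed, r)``, so a seed fixes every
output byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .coalescent import CoalescentModel, simulate_coalescent
from .config import SimulationJob
from .reconstruct import reconstruct_tree
from .trajectory import log_trajectory_grid, simulate_trajectory
from .treeio import TreeNode, write_nexus

__all__ = ["run_job", "replicate_rng"]

log = logging.getLogger("reactree")


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible stream for one replicate of one job."""
    return np.random.default_rng(np.random.SeedSequence((seed, replicate)))


@dataclass
class JobResult:
    forests: list[list[TreeNode]]
    trees_path: Optional[str] = None
    trajectory_path: Optional[str] = None


def run_job(
    job: SimulationJob,
    out_trees: Optional[str] = None,
    out_trajectory: Optional[str] = None,
) -> JobResult:
    """Run all replicates of a job and write the requested outputs."""
    if out_trees is None and out_trajectory is None:
        raise ValueError("at least one output must be requested")
    forests: list[list[TreeNode]] = []
    grids = []
    for rep in range(job.replicates):
        rng = replicate_rng(job.seed, rep)
        if isinstance(job.model, CoalescentModel):
            root = simulate_coalescent(job.model, rng)
            forests.append([root])
            log.info("replicate %d: coalescent tree with %d leaves",
                     rep, sum(1 for _ in root.leaves()))
        else:
            traj = simulate_trajectory(job.model, rng)
            log.info("replicate %d: %d events, %d samples",
                     rep, len(traj.events), traj.n_samples)
            forests.append(reconstruct_tree(traj, job.model, rng))
            if out_trajectory is not None:
                grid = log_trajectory_grid(traj, job.grid_points)
                grid.insert(0, "replicate", rep)
                grids.append(grid)
    result = JobResult(forests)
    if out_trees is not None:
        write_nexus(forests, out_trees, typed=True,
                    suppress_unary=not job.typed_newick)
        result.trees_path = str(out_trees)
    if out_trajectory is not None and grids:
        import pandas as pd

        table = pd.concat(grids, ignore_index=True)
        table.to_csv(out_trajectory, sep="\t", index=False, float_format="%.10g")
        result.trajectory_path = str(out_trajectory)
    return result
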