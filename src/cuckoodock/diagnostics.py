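"""Search-behavior measurement layer.

Implements the quantities used to characterize a stochastic docking search:

* distance sum (DS) — sum of pairwise Euclidean distances between the search
  agents' pose vectors, a proxy for search-space coverage;
* subset-DS rescaling by the pair-count ratio C(n_full,2)/C(n_subset,2);
* convergence fraction — index of the last best-energy improvement divided by
  the total number of energy evaluations (values near 1 mean the search was
  still improving late in the run);
* RMSD success rate against the 0.2 nm docking threshold;
* better/worse-set important-update bookkeeping and repeated-run summaries.

The DS norm deliberately mixes Angstrom (position), raw quaternion components
(orientation) and wrapped radians (torsions) in one Euclidean norm; a
block-normalized variant is available behind a flag for sensitivity checks but
is never the default.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .posemodel import PoseVector, wrap_angle

__all__ = [
    "SearchTrace",
    "RunSummary",
    "SUCCESS_THRESHOLD_NM",
    "distance_sum",
    "rescale_subset_ds",
    "convergence_fraction",
    "success_rate",
    "summarize_repeats",
    "find_breakthroughs",
    "write_trace_tsv",
    "plot_ds",
    "plot_updates",
]

#: docked pose within 0.2 nm (2 A) of the reference counts as a success
SUCCESS_THRESHOLD_NM = 0.2


@dataclasses.dataclass
class SearchTrace:
    """Per-run record of a search's observable behavior.

    ``best_energy`` holds the best-so-far energy after each counted scorer
    evaluation (non-increasing by construction).  Iteration-level rows record
    the evaluation index at the end of each iteration, the all-agent DS, the
    better-set DS (NaN where undefined, e.g. single-agent searches) and the
    cumulative important-update counters for the better and worse sets.
    """

    best_energy: np.ndarray = dataclasses.field(
        default_factory=lambda: np.empty(0)
    )
    n_evaluations: int = 0
    eval_index: list = dataclasses.field(default_factory=list)
    ds: list = dataclasses.field(default_factory=list)
    ds_better: list = dataclasses.field(default_factory=list)
    better_updates: list = dataclasses.field(default_factory=list)
    worse_updates: list = dataclasses.field(default_factory=list)

    def record_iteration(
        self,
        eval_index: int,
        ds: float,
        ds_better: float,
        better_updates: int,
        worse_updates: int,
    ) -> None:
        if self.eval_index and eval_index <= self.eval_index[-1]:
            return  # nothing evaluated since the last record
        self.eval_index.append(int(eval_index))
        self.ds.append(float(ds))
        self.ds_better.append(float(ds_better))
        self.better_updates.append(int(better_updates))
        self.worse_updates.append(int(worse_updates))

    @property
    def n_iterations(self) -> int:
        return len(self.eval_index)

    def iterations_frame(self) -> pd.DataFrame:
        best = np.asarray(self.best_energy)
        rows = {
            "eval_index": self.eval_index,
            "best_energy": [
                best[i - 1] if 0 < i <= best.size else np.nan
                for i in self.eval_index
            ],
            "ds": self.ds,
            "ds_better": self.ds_better,
            "better_updates": self.better_updates,
            "worse_updates": self.worse_updates,
        }
        return pd.DataFrame(rows)


@dataclasses.dataclass
class RunSummary:
    """One repeated-run record: final energy, pose accuracy and convergence."""

    final_energy: float
    rmsd_nm: float | None = None
    convergence: float | None = None
    wall_time: float | None = None

    @property
    def success(self) -> bool | None:
        if self.rmsd_nm is None:
            return None
        return self.rmsd_nm < SUCCESS_THRESHOLD_NM


def _pose_blocks(poses: Sequence[PoseVector]):
    pos = np.stack([p.position for p in poses])
    quat = np.stack([p.orientation for p in poses])
    tors = (
        np.stack([p.torsions for p in poses])
        if poses[0].n_torsions
        else np.zeros((len(poses), 0))
    )
    return pos, quat, tors


def distance_sum(poses: Sequence[PoseVector], normalized: bool = False) -> float:
    """DS = sum over unordered agent pairs of ||X_i - X_j||.

    Pose-vector differences use raw positions (A), raw quaternion components
    and wrapped torsion differences (rad).  With ``normalized=True`` each block
    is divided by its scale (largest position spread, 1 for quaternions, pi for
    torsions) — a sensitivity variant only, never the default.
    """
    if len(poses) < 2:
        raise ValueError("distance sum needs at least 2 poses")
    dims = {p.size for p in poses}
    if len(dims) != 1:
        raise ValueError("poses must share one dimensionality")
    pos, quat, tors = _pose_blocks(poses)
    if normalized:
        spread = np.max(np.abs(pos - pos.mean(axis=0)))
        pos = pos / max(spread, 1e-12)
        tors = tors / np.pi
    dp = pos[:, None, :] - pos[None, :, :]
    dq = quat[:, None, :] - quat[None, :, :]
    d2 = (dp * dp).sum(-1) + (dq * dq).sum(-1)
    if tors.shape[1]:
        dt = wrap_angle(tors[:, None, :] - tors[None, :, :])
        d2 = d2 + (dt * dt).sum(-1)
    dist = np.sqrt(d2)
    iu = np.triu_indices(len(poses), k=1)
    return float(dist[iu].sum())


def rescale_subset_ds(ds_subset: float, n_subset: int, n_full: int) -> float:
    """Rescale a subset DS by the pair-count ratio C(n_full,2)/C(n_subset,2).

    Used to put the better-set DS (e.g. 6 agents) on the scale of the full
    population (e.g. 8 agents) for visual comparison.
    """
    if n_subset < 2:
        raise ValueError("subset must contain at least 2 agents")
    if n_subset > n_full:
        raise ValueError("subset cannot exceed the full population")
    factor = math.comb(n_full, 2) / math.comb(n_subset, 2)
    return ds_subset * factor


def convergence_fraction(trace: SearchTrace) -> float:
    """(1-based index of the last best-so-far improvement) / total evaluations."""
    best = np.asarray(trace.best_energy, dtype=float)
    if best.size == 0:
        raise ValueError("empty trace")
    improved = np.empty(best.size, dtype=bool)
    improved[0] = True  # first evaluation establishes the incumbent
    improved[1:] = best[1:] < best[:-1]
    last = int(np.nonzero(improved)[0][-1]) + 1
    total = trace.n_evaluations if trace.n_evaluations else best.size
    return last / total


def success_rate(summaries: Sequence[RunSummary]) -> float:
    """Percentage of runs with RMSD strictly below 0.2 nm.

    Runs without a reference RMSD are excluded (with a warning) and the
    denominator adjusted.
    """
    usable = [s for s in summaries if s.rmsd_nm is not None]
    if len(usable) < len(summaries):
        warnings.warn(
            f"{len(summaries) - len(usable)} run(s) without a reference RMSD "
            "excluded from the success rate"
        )
    if not usable:
        raise ValueError("no runs with a reference RMSD")
    return 100.0 * sum(s.success for s in usable) / len(usable)


def summarize_repeats(per_run: pd.DataFrame, method_col: str = "method") -> pd.DataFrame:
    """Per-method mean +/- sample sd across repeats for every numeric metric.

    ``per_run`` holds one row per run with a method column and numeric metric
    columns (rmsd_nm, affinity, convergence, ...).  Returns a tidy frame with
    columns (method, metric, mean, sd, n).  Requires >= 2 repeats per method.
    """
    if method_col not in per_run.columns:
        raise ValueError(f"missing {method_col!r} column")
    metrics = [
        c
        for c in per_run.columns
        if c != method_col and pd.api.types.is_numeric_dtype(per_run[c])
    ]
    rows = []
    for method, group in per_run.groupby(method_col, sort=False):
        if len(group) < 2:
            raise ValueError(f"method {method!r} has fewer than 2 repeats")
        for metric in metrics:
            vals = group[metric].to_numpy(dtype=float)
            rows.append(
                {
                    "method": method,
                    "metric": metric,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)),
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def find_breakthroughs(
    trace: SearchTrace, window: int = 50, min_better: int = 5
) -> list[int]:
    """Iteration indices where a worse-set important update is followed, within
    ``window`` iterations, by at least ``min_better`` better-set updates.

    This is the "breakthrough" pattern: the worse set's DE rebuild discovers a
    new low-energy region, the solution enters the better set on re-ranking,
    and local exploitation around it then drives a burst of better-set updates.
    """
    worse = np.asarray(trace.worse_updates, dtype=int)
    better = np.asarray(trace.better_updates, dtype=int)
    if worse.size == 0:
        return []
    hits = []
    jumps = np.nonzero(np.diff(np.concatenate([[0], worse])) > 0)[0]
    for t in jumps:
        end = min(t + window, better.size - 1)
        if better[end] - better[t] >= min_better:
            hits.append(int(t))
    return hits


def write_trace_tsv(trace: SearchTrace, path) -> None:
    """Write the per-iteration trace as a TSV.

    Columns: eval_index, best_energy, ds, better_updates, worse_updates.
    """
    frame = trace.iterations_frame()
    frame[["eval_index", "best_energy", "ds", "better_updates", "worse_updates"]].to_csv(
        path, sep="\t", index=False
    )


def plot_ds(traces, labels, path) -> None:
    """DS-vs-evaluations comparison plot (PNG). Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for trace, label in zip(traces, labels):
        ax.plot(trace.eval_index, trace.ds, label=label)
    ax.set_xlabel("energy evaluations")
    ax.set_ylabel("distance sum")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_updates(trace: SearchTrace, path) -> None:
    """Cumulative better/worse-set update curves (PNG). Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(trace.eval_index, trace.better_updates, label="better set")
    ax.plot(trace.eval_index, trace.worse_updates, label="worse set")
    ax.set_xlabel("energy evaluations")
    ax.set_ylabel("cumulative important updates")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
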