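"""Sample-size stability of variance-component and ICC estimates.

For each synthetic dataset, variance-component proportions and ICC(A,1) are
recomputed on growing subject subsets (the default grid runs from 10 to 300
in steps of 1). Given a ground-truth proportion ``g`` from the full source
dataset and a corridor of stability ``[g - w, g + w]``, the *point of
stability* (PoS) of a trajectory is the smallest sample size from which the
estimate never again leaves the corridor; a trajectory that never settles is
assigned the grid maximum and one that never leaves the corridor the grid
minimum. Percentiles (80/90/95) of the PoS distribution across datasets give
the *critical sample size* for a chosen precision and confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reliability import icc_a1, variance_components

__all__ = [
    "CorridorSpec",
    "default_grid",
    "trajectory",
    "ensemble_trajectories",
    "point_of_stability",
    "pos_table",
    "critical_n",
    "critical_n_table",
    "component_icc_correlation",
    "stability_report",
    "COMPONENTS",
    "DEFAULT_WIDTHS",
    "DEFAULT_PERCENTILES",
]

COMPONENTS = ("between", "within", "error")
DEFAULT_WIDTHS = (0.025, 0.05, 0.075, 0.1, 0.15, 0.2)
DEFAULT_PERCENTILES = (80, 90, 95)


@dataclass(frozen=True)
class CorridorSpec:
    """Corridor of stability ``[g - w, g + w]`` around ground truth ``g``."""

    g: float
    w: float

    def __post_init__(self):
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("g must be a proportion in [0, 1]")
        if self.w <= 0:
            raise ValueError("w must be positive")

    @property
    def low(self) -> float:
        return self.g - self.w

    @property
    def high(self) -> float:
        return self.g + self.w


def default_grid(n_min: int = 10, n_max: int = 300, step: int = 1) -> np.ndarray:
    return np.arange(n_min, n_max + 1, step)


def trajectory(dataset, grid=None) -> pd.DataFrame:
    """Variance proportions and ICC(A,1) on nested subject subsets.

    ``dataset`` is an n x 2 matrix (or a frame with session1/session2
    columns) with at least ``grid.max()`` subjects; sample size ``n`` uses
    the first ``n`` subjects, so the trajectory is a growing sequence over
    one fixed dataset.
    """
    grid = default_grid() if grid is None else np.asarray(grid)
    if isinstance(dataset, pd.DataFrame):
        cols = [c for c in ("session1", "session2") if c in dataset.columns]
        X = dataset[cols].to_numpy(dtype=float) if cols else dataset.to_numpy(dtype=float)
    else:
        X = np.asarray(dataset, dtype=float)
    if X.shape[0] < grid.max():
        raise ValueError(
            f"dataset has {X.shape[0]} subjects but the grid needs {grid.max()}")
    rows = []
    for n in grid:
        vc = variance_components(X[:n])
        rows.append({
            "n": int(n),
            "between": vc.proportions[0],
            "within": vc.proportions[1],
            "error": vc.proportions[2],
            "icc_a1": icc_a1(X[:n], ci=False).icc_a1,
        })
    return pd.DataFrame(rows)


def ensemble_trajectories(ensemble: pd.DataFrame, grid=None) -> pd.DataFrame:
    """Trajectories for every dataset in a long-format ensemble table."""
    frames = []
    for did, grp in ensemble.groupby("dataset_id"):
        traj = trajectory(grp.sort_values("subject"), grid)
        traj.insert(0, "dataset_id", did)
        frames.append(traj)
    return pd.concat(frames, ignore_index=True)


def point_of_stability(values, corridor: CorridorSpec, grid=None) -> int:
    """Smallest grid n from which the trajectory stays inside the corridor.

    Returns the grid maximum when the trajectory never settles (including
    when its final value is outside the corridor) and the grid minimum when
    it never deviates.
    """
    values = np.asarray(values, dtype=float)
    grid = default_grid() if grid is None else np.asarray(grid)
    if values.shape[0] != grid.shape[0]:
        raise ValueError("trajectory and grid lengths differ")
    outside = (values < corridor.low) | (values > corridor.high)
    if not outside.any():
        return int(grid[0])
    last_out = np.max(np.nonzero(outside)[0])
    if last_out == len(grid) - 1:
        return int(grid[-1])
    return int(grid[last_out + 1])


def pos_table(trajectories: pd.DataFrame, ground_truth: dict,
              widths=DEFAULT_WIDTHS, grid=None) -> pd.DataFrame:
    """Points of stability per (dataset, component, corridor half-width).

    ``ground_truth`` maps component name -> g (proportions from the full
    source dataset).
    """
    grid_arr = (default_grid() if grid is None else np.asarray(grid))
    rows = []
    for did, grp in trajectories.groupby("dataset_id"):
        grp = grp.sort_values("n")
        for comp in COMPONENTS:
            vals = grp[comp].to_numpy()
            for w in widths:
                cor = CorridorSpec(g=ground_truth[comp], w=w)
                rows.append({"dataset_id": did, "component": comp, "w": w,
                             "pos": point_of_stability(vals, cor, grid_arr)})
    return pd.DataFrame(rows)


def critical_n(pos_values, percentile: float) -> float:
    """Empirical percentile of a PoS distribution (linear interpolation)."""
    pos_values = np.asarray(pos_values, dtype=float)
    if pos_values.size == 0:
        raise ValueError("empty PoS vector")
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    return float(np.percentile(pos_values, percentile, method="linear"))


def critical_n_table(pos: pd.DataFrame,
                     percentiles=DEFAULT_PERCENTILES) -> pd.DataFrame:
    """Critical sample sizes per (component, w, percentile)."""
    rows = []
    group_cols = [c for c in ("measure", "noise_sd") if c in pos.columns]
    for key, grp in pos.groupby(group_cols + ["component", "w"]):
        meta = dict(zip(group_cols + ["component", "w"], key))
        for p in percentiles:
            rows.append({**meta, "percentile": p,
                         "critical_n": critical_n(grp["pos"], p)})
    return pd.DataFrame(rows)


def component_icc_correlation(trajectories: pd.DataFrame,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of each component with ICC(A,1) across datasets.

    At every sample size n the rank correlation between a variance
    component's proportion and ICC(A,1) is computed across datasets; p
    values are Bonferroni-corrected over the whole (component x n) sweep
    (times measures when present). Constant components are flagged
    undefined.
    """
    group_cols = [c for c in ("measure",) if c in trajectories.columns]
    rows = []
    for key, grp in trajectories.groupby(group_cols + ["n"]):
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(group_cols + ["n"], key))
        if grp["dataset_id"].nunique() < 3:
            raise ValueError("need at least 3 datasets per sample size")
        for comp in COMPONENTS:
            x = grp[comp].to_numpy()
            y = grp["icc_a1"].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({**meta, "component": comp, "rho": np.nan,
                             "p": np.nan, "undefined": True})
                continue
            res = stats.spearmanr(x, y)
            rows.append({**meta, "component": comp,
                         "rho": float(res.statistic), "p": float(res.pvalue),
                         "undefined": False})
    out = pd.DataFrame(rows)
    n_tests = int((~out["undefined"]).sum())
    out["p_bonferroni"] = np.minimum(out["p"] * n_tests, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    out.loc[out["undefined"], "significant"] = False
    return out


def stability_report(pos_by_noise: pd.DataFrame,
                     percentiles=DEFAULT_PERCENTILES,
                     grid_max: int = 300) -> dict:
    """Summary tables across noise levels.

    ``pos_by_noise`` is a PoS long table with a ``noise_sd`` column.
    Returns per-component critical-N summaries (mean/median/SD over any
    measures present) and, when two or more noise levels are available, the
    share of never-stabilising trajectories (PoS equal to the grid maximum)
    per noise level as a monotonicity summary.
    """
    crit = critical_n_table(pos_by_noise, percentiles)
    agg_cols = ["noise_sd", "component", "w", "percentile"]
    summary = (crit.groupby(agg_cols)["critical_n"]
               .agg(["mean", "median", "std"]).reset_index())
    noise_levels = sorted(pos_by_noise["noise_sd"].unique())
    monotonicity = pd.DataFrame()
    if len(noise_levels) >= 2:
        monotonicity = (pos_by_noise.assign(at_max=pos_by_noise["pos"] >= grid_max)
                        .groupby(["noise_sd", "component"])["at_max"]
                        .mean().rename("share_pos_at_max").reset_index())
    mean_pos = (pos_by_noise.groupby(["noise_sd", "component"])["pos"]
                .mean().rename("mean_pos").reset_index())
    return {"critical_n": crit, "summary": summary,
            "monotonicity": monotonicity, "mean_pos": mean_pos}
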