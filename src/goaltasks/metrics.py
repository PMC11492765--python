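"""Target-frame performance statistics, trial filters, and the pre-strike
trajectory analysis.

Accuracy and consistency are separated the classic way: mean radial error
(MRE) is the mean distance of hits from the bullseye; bivariate variable
error (BVE) is the RMS distance of hits from their own centroid; centroid
bias is the distance from the bullseye to the hit centroid.  Note that with
MRE defined as a mean of norms, ``MRE^2 = bias^2 + BVE^2`` does *not* hold;
the triangle inequality ``MRE <= bias + BVE`` does, and the RMS variant
(:func:`rmse`) satisfies the exact Pythagorean split — it is provided as an
auxiliary metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GoalFunction, InputError, TrialBlock
from .tnc import SearchGrid, t_cost


@dataclass
class TrajectorySeries:
    """Uniformly sampled tracker series ending at the strike.

    ``strike_index`` marks the execution sample; positions are metres,
    velocities m/s, time strictly increasing in seconds.
    """

    t: np.ndarray
    position: np.ndarray  # (n, 3)
    velocity: np.ndarray  # (n, 3)
    strike_index: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.velocity = np.atleast_2d(np.asarray(self.velocity, dtype=float))
        n = self.t.size
        if n < 2:
            raise InputError("trajectory needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            raise InputError("time stamps must be strictly increasing")
        if self.position.shape != (n, 3) or self.velocity.shape != (n, 3):
            raise InputError("position/velocity must be (n, 3)")
        if not 0 <= self.strike_index < n:
            raise InputError("strike index out of range")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# target-frame statistics
# ---------------------------------------------------------------------------


def _hits(hits) -> np.ndarray:
    hits = np.atleast_2d(np.asarray(hits, dtype=float))
    if hits.shape[0] < 1 or not np.all(np.isfinite(hits)):
        raise InputError("hits must be a nonempty finite (n, 2) array")
    return hits


def mre(hits) -> float:
    """Mean radial error: mean distance from the bullseye (origin)."""
    h = _hits(hits)
    return float(np.mean(np.linalg.norm(h, axis=1)))


def rmse(hits) -> float:
    """RMS radial error (auxiliary): satisfies rmse^2 = bias^2 + bve^2."""
    h = _hits(hits)
    return float(np.sqrt(np.mean(np.sum(h**2, axis=1))))


def bve(hits) -> float:
    """Bivariate variable error: RMS distance of hits from their centroid."""
    h = _hits(hits)
    if h.shape[0] < 2:
        raise InputError("BVE needs at least two hits")
    centered = h - h.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))


def centroid_bias(hits) -> float:
    """Distance from the bullseye to the centroid of hits."""
    h = _hits(hits)
    return float(np.linalg.norm(h.mean(axis=0)))


def centroid_bias_execution(
    block_or_U, gf: GoalFunction, grid: SearchGrid | None = None,
    t_mode: str = "auto",
) -> np.ndarray:
    """Execution-space centroid bias, per variable: observed centroid minus
    the T-cost argmin centroid (the best grid location for the cloud)."""
    if isinstance(block_or_U, TrialBlock):
        U = block_or_U.U[block_or_U.active_mask()]
    else:
        U = np.atleast_2d(np.asarray(block_or_U, dtype=float))
    _, _, argmin_c = t_cost(U, gf, grid=grid, mode=t_mode)
    return U.mean(axis=0) - argmin_c


# ---------------------------------------------------------------------------
# trial filters
# ---------------------------------------------------------------------------

GROSS_ERROR_RADIUS_MULTIPLE = 15.0
OUTLIER_SD = 3.0


def filter_trials(block: TrialBlock, gf: GoalFunction) -> dict:
    """Flag gross-error and outlier trials; returns stage counts.

    Stage 1 (projectile tasks BA/RS only, where falling short of the target
    produces huge distances): flag errors above 15x the target radius.
    Stage 2: flag errors more than 3 SDs from the mean of the trials that
    survive stage 1.  Flags are recomputed deterministically from the error
    cache, so re-running on a filtered block changes nothing (idempotent).
    Gross misses (infinite error) are flagged first, with stage 1.
    """
    if np.any(np.isnan(block.errors)):
        raise InputError("score the block before filtering")
    e = block.errors
    misfire = block.misfire
    stage1 = np.zeros(block.n, dtype=bool)
    if block.task_id in ("BA", "RS"):
        stage1 = e > GROSS_ERROR_RADIUS_MULTIPLE * gf.target_radius
    stage1 |= ~np.isfinite(e)
    remaining = ~stage1 & ~misfire
    stage2 = np.zeros(block.n, dtype=bool)
    if remaining.sum() >= 2:
        mu = e[remaining].mean()
        sd = e[remaining].std(ddof=1)
        if sd > 0:
            stage2 = remaining & (np.abs(e - mu) > OUTLIER_SD * sd)
    block.excluded = stage1 | stage2
    return {
        "stage1": int(stage1[~misfire].sum()),
        "stage2": int(stage2.sum()),
        "excluded_total": int(block.excluded.sum()),
    }


# ---------------------------------------------------------------------------
# pre-strike trajectory analysis
# ---------------------------------------------------------------------------

PRE_STRIKE_WINDOW = 1.0  # s


def _execution_rows(traj: TrajectorySeries, gf: GoalFunction,
                    trial_u: np.ndarray | None) -> np.ndarray:
    """Instantaneous execution vectors along the trajectory: velocity
    components, with any position-based variable (PB hit height) frozen at
    the trial's value."""
    v = traj.velocity
    if gf.task_id == "RS":
        return v.copy()
    if gf.task_id == "PB":
        if trial_u is None:
            raise InputError("PB trajectory analysis needs the trial's d")
        rows = np.column_stack([v[:, 0], v[:, 2], np.full(v.shape[0],
                                                          trial_u[2])])
        return rows
    raise InputError(f"trajectory analysis not defined for {gf.task_id}")


def on_target_time(
    traj: TrajectorySeries,
    gf: GoalFunction,
    rt: float | None = None,
    trial_u: np.ndarray | None = None,
) -> float | None:
    """Uninterrupted pre-strike time spent moving with on-target velocities.

    Within the 1 s window before the strike, finds the longest contiguous
    run of samples, ending at the strike, whose instantaneous execution
    variables map to errors below the target radius; returns its duration.
    Returns None (not applicable) when the strike itself missed.  A run of
    just the strike sample counts one sample period.  Windows are evaluated
    on the sampled grid without interpolation.
    """
    rt = gf.target_radius if rt is None else rt
    i1 = traj.strike_index
    rows = _execution_rows(traj, gf, trial_u)
    if not gf.error_batch(rows[i1 : i1 + 1])[0] < rt:
        return None
    i0 = int(np.searchsorted(traj.t, traj.t[i1] - PRE_STRIKE_WINDOW))
    on = gf.error_batch(rows[i0 : i1 + 1]) < rt
    k = i1
    while k - 1 >= i0 and on[k - 1 - i0]:
        k -= 1
    if k == i1:
        return float(traj.dt)
    return float(traj.t[i1] - traj.t[k])


def mean_lateral_speed_premovement(
    traj: TrajectorySeries, speed_fraction: float = 0.2
) -> tuple[float, float] | None:
    """Mean lateral (x) velocity over the pre-execution movement window.

    The window is the uninterrupted run of samples, ending at the strike,
    with speed above ``speed_fraction`` (20 %) of the strike speed.  Returns
    ``(mean vx, mean |vx|)`` — both conventions are in use — or None when
    the strike speed is zero.
    """
    i1 = traj.strike_index
    speeds = np.linalg.norm(traj.velocity, axis=1)
    strike_speed = speeds[i1]
    if not strike_speed > 0:
        return None
    moving = speeds > speed_fraction * strike_speed
    k = i1
    while k - 1 >= 0 and moving[k - 1]:
        k -= 1
    vx = traj.velocity[k : i1 + 1, 0]
    return float(np.mean(vx)), float(np.mean(np.abs(vx)))


# ---------------------------------------------------------------------------
# per-block summary
# ---------------------------------------------------------------------------


def block_metrics(
    block: TrialBlock,
    gf: GoalFunction,
    grid: SearchGrid | None = None,
    tnc_result=None,
) -> dict:
    """Flat per-block metrics row (Table-style naming) for export.

    Includes mean error, target-frame MRE/bias/BVE where the task has a
    planar target, execution-variable means/SDs, and TNC costs when a
    :class:`goaltasks.tnc.TNCResult` is supplied.
    """
    from .tnc import tnc as run_tnc

    mask = block.active_mask() & np.isfinite(block.errors)
    e = block.errors[mask]
    row: dict = {
        "task_id": block.task_id,
        "condition": block.condition,
        "block_index": block.block_index,
        "n_trials": int(mask.sum()),
        "n_misfire": int(block.misfire.sum()),
        "n_excluded": int(block.excluded.sum()),
        "mean_error": float(np.mean(e)) if e.size else np.nan,
    }
    if block.task_id in ("BA", "RS"):
        hits = np.array([gf.residual(u) for u in block.U[mask]])
        row["MRE"] = mre(hits)
        row["bias"] = centroid_bias(hits)
        if hits.shape[0] >= 2:
            row["BVE"] = bve(hits)
    names = block.variable_names
    U = block.U[mask]
    for j, name in enumerate(names):
        row[f"mu_{name}"] = float(U[:, j].mean())
        row[f"sigma_{name}"] = float(U[:, j].std(ddof=1)) if U.shape[0] > 1 else 0.0
    if tnc_result is None and grid is not None:
        tnc_result = run_tnc(block, gf, grid=grid)
    if tnc_result is not None:
        row["T"] = tnc_result.T
        row["N"] = tnc_result.N
        row["C"] = tnc_result.C
        for name, val in tnc_result.N_by_variable.items():
            row[f"N_{name}"] = val
    return row
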