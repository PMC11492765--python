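"""Subject-specific task adjustment in three sequential steps.

Step 1 finds the smallest uniform velocity scale ``kv >= 1`` bringing the
centroid of the velocity-based execution variables into a desired operating
region (so a slow-moving subject's effective speeds match the task's
reference range).  Step 2 resizes the target radius ``rt`` to the subject's
trial-to-trial variability: after removing centroid bias with the T-cost
algorithm, the N-cost of the remainder must satisfy ``N / rt <= e_max``.
Step 3 chooses a visual error modification vector ``c`` that shrinks each
trial's fluctuation from the solution manifold, ``u_r = u* + c (u - u*)``,
until the mean displayed error satisfies ``mean / rt <= e_max``; axis-
specific policies modify a single component, and a magnitude-preserving
variant keeps the observed movement magnitude (for the punching bag this
preserves swing height while shrinking direction error).

All steps are computed from one prior block of observations and applied
forward; they modify what the subject *sees*, never the goal function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import (
    GoalFunction,
    InfeasibleError,
    InputError,
    TrialBlock,
    VELOCITY_COLS,
)
from .tnc import SearchGrid, n_cost, t_cost


@dataclass
class AdjustmentParams:
    """Parameters produced by the three-step adjustment."""

    kv: float  # uniform velocity scale, >= 1
    rt: float  # adjusted target radius (m, or deg for PB)
    c: np.ndarray | None  # per-variable error-modification vector
    v_min: np.ndarray | None = None
    e_max: float = 0.4
    policy: str = "uniform"
    feasible: bool = True
    mean_modified_error: float = np.nan

    def to_dict(self) -> dict:
        return {
            "kv": float(self.kv),
            "rt": float(self.rt),
            "c": None if self.c is None else [float(x) for x in self.c],
            "v_min": None if self.v_min is None else [float(x) for x in self.v_min],
            "e_max": float(self.e_max),
            "policy": self.policy,
            "feasible": bool(self.feasible),
            "mean_modified_error": float(self.mean_modified_error),
        }


@dataclass(frozen=True)
class FluctuationDecomposition:
    """One trial split into its nearest zero-error execution and the
    fluctuation from it."""

    u_star: np.ndarray
    d: np.ndarray

    @property
    def fluctuation_norm(self) -> float:
        return float(np.linalg.norm(self.d))


# ---------------------------------------------------------------------------
# solution-manifold projection
# ---------------------------------------------------------------------------


def project_to_manifold(
    u: np.ndarray,
    gf: GoalFunction,
    standardize: np.ndarray | None = None,
    n_lattice: int = 7,
    n_starts: int = 3,
    tol_factor: float = 1e-6,
) -> np.ndarray:
    """Nearest zero-error execution ``u*`` to ``u`` (Euclidean by default).

    Solves ``min ||x - u||^2  s.t.  residual(x) = 0`` with SLSQP, multi-start
    from ``u`` itself plus the most promising points of a coarse lattice over
    the goal function's bounds.  ``standardize`` (per-variable scales, e.g.
    block SDs) switches the metric to weighted Euclidean for mixed-unit
    tasks.  The result satisfies ``error(u*) <= 1e-6 * target_radius``.
    """
    u = np.asarray(u, dtype=float).ravel()
    m = gf.arity
    w = np.ones(m) if standardize is None else 1.0 / np.asarray(standardize, float)
    bounds = gf.bounds
    tol = tol_factor * gf.target_radius

    def dist2(x: np.ndarray) -> float:
        return float(np.sum((w * (x - u)) ** 2))

    # seed candidates: the observed point, then lattice points that are both
    # near the manifold (low error) and near u
    grids = [np.linspace(lo, hi, n_lattice) for lo, hi in bounds]
    mesh = np.meshgrid(*grids, indexing="ij")
    lattice = np.column_stack([mm.ravel() for mm in mesh])
    err = gf.error_batch(lattice)
    finite = np.isfinite(err)
    lattice, err = lattice[finite], err[finite]
    score = err / max(gf.target_radius, 1e-12) + np.linalg.norm(
        w * (lattice - u), axis=1
    )
    seeds = [u] + [lattice[i] for i in np.argsort(score)[:n_starts]]

    best, best_d = None, np.inf
    for seed in seeds:
        try:
            res = optimize.minimize(
                dist2,
                np.clip(seed, bounds[:, 0], bounds[:, 1]),
                method="SLSQP",
                bounds=bounds,
                constraints=[{"type": "eq", "fun": gf.residual}],
                options={"maxiter": 200, "ftol": 1e-14},
            )
        except (InputError, Exception) as exc:  # pragma: no cover - defensive
            if isinstance(exc, KeyboardInterrupt):
                raise
            continue
        x = res.x
        if gf.error(x) <= tol and dist2(x) < best_d:
            best, best_d = x, dist2(x)
    if best is None:
        raise InfeasibleError(
            "no zero-error execution found within the search bounds; "
            "check the environment calibration"
        )
    return best


def decompose_fluctuation(
    u: np.ndarray, gf: GoalFunction, **kwargs
) -> FluctuationDecomposition:
    u = np.asarray(u, dtype=float).ravel()
    u_star = project_to_manifold(u, gf, **kwargs)
    return FluctuationDecomposition(u_star=u_star, d=u - u_star)


# ---------------------------------------------------------------------------
# step 1: velocity scaling
# ---------------------------------------------------------------------------


def compute_velocity_scale(
    U_or_block,
    v_min: np.ndarray,
    task_id: str | None = None,
    velocity_cols: tuple | None = None,
) -> float:
    """Smallest ``kv >= 1`` whose scaled centroid meets every bound axis.

    ``v_min`` aligns with the task's velocity columns.  Comparisons are
    oriented by the sign of each bound: a negative bound (e.g. forward
    velocity, -z forward) means *at least as negative as*; zero bounds are
    inactive.  A centroid of zero (or of the wrong sign) on an active axis
    cannot be scaled into the region and raises :class:`InfeasibleError`.
    """
    if isinstance(U_or_block, TrialBlock):
        task_id = U_or_block.task_id
        U = U_or_block.U[U_or_block.active_mask()]
    else:
        U = np.atleast_2d(np.asarray(U_or_block, dtype=float))
    if velocity_cols is None:
        if task_id is None:
            raise InputError("need task_id or velocity_cols")
        velocity_cols = VELOCITY_COLS[task_id]
    v_min = np.asarray(v_min, dtype=float).ravel()
    if len(v_min) != len(velocity_cols):
        raise InputError("v_min length must match the velocity columns")
    centroid = U[:, list(velocity_cols)].mean(axis=0)
    kv = 1.0
    for c, vm in zip(centroid, v_min):
        if vm == 0.0:
            continue
        if c == 0.0 or np.sign(c) != np.sign(vm):
            raise InfeasibleError(
                f"centroid {c:.3g} cannot be scaled to reach bound {vm:.3g}"
            )
        kv = max(kv, vm / c)
    return float(kv)


def scale_velocities(U: np.ndarray, kv: float, task_id: str) -> np.ndarray:
    """Apply the uniform velocity scale to the task's velocity columns."""
    out = np.atleast_2d(np.asarray(U, dtype=float)).copy()
    cols = list(VELOCITY_COLS[task_id])
    out[:, cols] *= kv
    return out


# ---------------------------------------------------------------------------
# step 2: target resizing
# ---------------------------------------------------------------------------


def resize_target(
    U_scaled,
    gf: GoalFunction,
    grid: SearchGrid | None = None,
    e_max: float = 0.4,
    current_radius: float | None = None,
    t_mode: str = "auto",
) -> float:
    """Smallest target radius with TTV-related error below ``e_max``.

    Centroid bias is first removed with the T-cost algorithm (assuming the
    subject can learn the bias away); the N-cost of the T-adjusted set then
    measures the irreducible effect of motor noise, and the radius grows to
    ``N / e_max`` if needed.  The error metrics here are radius-independent,
    so N needs no recomputation per candidate radius.  Never shrinks the
    target below its configured baseline.
    """
    if not e_max > 0:
        raise InputError("e_max must be > 0")
    r0 = gf.target_radius if current_radius is None else current_radius
    _, U_star_T, _ = t_cost(U_scaled, gf, grid=grid, mode=t_mode)
    N, _, _ = n_cost(U_star_T, gf)
    return float(max(r0, N / e_max))


# ---------------------------------------------------------------------------
# step 3: visual error modification
# ---------------------------------------------------------------------------


def apply_visual_error_modification(
    u: np.ndarray,
    gf: GoalFunction,
    c: np.ndarray,
    u_star: np.ndarray | None = None,
    **proj_kwargs,
) -> np.ndarray:
    """Displayed execution ``u_r = u* + c (u - u*)`` (element-wise).

    ``c = 1`` is the identity, ``c = 0`` lands on the solution manifold;
    components of ``c`` may differ to shrink selected error axes only.
    """
    u = np.asarray(u, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if c.shape != u.shape:
        raise InputError("c must have one component per execution variable")
    if np.any(c < 0):
        raise InputError("c components must be nonnegative")
    if u_star is None:
        u_star = project_to_manifold(u, gf, **proj_kwargs)
    return u_star + c * (u - u_star)


def apply_speed_preserving_modification(
    u: np.ndarray,
    gf: GoalFunction,
    c: np.ndarray,
    u_star: np.ndarray | None = None,
    mode: str = "velocity",
    **proj_kwargs,
) -> np.ndarray:
    """Error modification that preserves the observed movement magnitude.

    The shrunken execution ``w = u* + c (u - u*)`` is rescaled so the result
    keeps the magnitude of the observed ``u``.  ``mode="velocity"`` (default)
    restores the observed speed on the velocity components and leaves
    position components untouched (their ``c`` must be 1); this preserves
    both ``||u||`` and, for the punching bag, the swing height exactly,
    while shrinking direction error.  ``mode="full"`` rescales the whole
    vector to ``||u||``.
    """
    u = np.asarray(u, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if np.any(c < 0):
        raise InputError("c components must be nonnegative")
    if u_star is None:
        u_star = project_to_manifold(u, gf, **proj_kwargs)
    w = u_star + c * (u - u_star)
    if mode == "full":
        norm_w = float(np.linalg.norm(w))
        if norm_w == 0.0:
            raise InfeasibleError(
                "zero-norm intermediate in magnitude-preserving rescaling"
            )
        return float(np.linalg.norm(u)) / norm_w * w
    if mode != "velocity":
        raise InputError(f"unknown mode {mode!r}")
    vel = list(VELOCITY_COLS[gf.task_id])
    pos = [j for j in range(gf.arity) if j not in vel]
    if pos and not np.allclose(c[pos], 1.0):
        raise InputError(
            "velocity mode requires c = 1 on position-based components"
        )
    if not vel:
        return w
    speed_obs = float(np.linalg.norm(u[vel]))
    speed_w = float(np.linalg.norm(w[vel]))
    if speed_w == 0.0:
        raise InfeasibleError("zero-norm velocity intermediate in rescaling")
    out = w.copy()
    out[vel] = speed_obs / speed_w * w[vel]
    return out


@dataclass
class ModificationSelection:
    """Result of the grid search for the error-modification vector."""

    c: np.ndarray | None
    feasible: bool
    c_value: float | None
    mean_modified_error: float
    policy: str


def _policy_vector(policy, value: float, m: int) -> np.ndarray:
    if policy == "uniform":
        return np.full(m, value)
    if policy == "pb-speed-preserving":
        c = np.ones(m)
        c[:-1] = value
        return c
    if isinstance(policy, tuple) and policy[0] == "axis":
        c = np.ones(m)
        c[policy[1]] = value
        return c
    raise InputError(f"unknown policy {policy!r}")


def select_modification_vector(
    U_scaled,
    gf: GoalFunction,
    rt: float,
    e_max: float = 0.4,
    policy="uniform",
    step: float = 0.05,
    u_stars: np.ndarray | None = None,
    **proj_kwargs,
) -> ModificationSelection:
    """Largest-first grid search for ``c`` meeting the mean-error constraint.

    Scans candidate component values 1.00, 0.95, ..., 0.00 and returns the
    largest (least manipulative) ``c`` in the policy's family whose mean
    modified error over the block satisfies ``mean / rt <= e_max``.
    Single-axis policies can be infeasible when the untouched axes carry an
    error floor above the threshold; this is reported, not raised.
    """
    U = np.atleast_2d(np.asarray(
        U_scaled.U[U_scaled.active_mask()] if isinstance(U_scaled, TrialBlock)
        else U_scaled, dtype=float))
    n, m = U.shape
    if u_stars is None:
        u_stars = np.array(
            [project_to_manifold(U[i], gf, **proj_kwargs) for i in range(n)]
        )
    D = U - u_stars
    values = np.round(np.arange(1.0, -step / 2.0, -step), 10)
    speed_preserving = policy == "pb-speed-preserving"
    best = None
    for v in values:
        c = _policy_vector(policy, float(v), m)
        if speed_preserving:
            rows = [
                apply_speed_preserving_modification(
                    U[i], gf, c, u_star=u_stars[i]
                )
                for i in range(n)
            ]
            modified = np.array(rows)
        else:
            modified = u_stars + c * D
        e = gf.error_batch(modified)
        mean = float(np.mean(e)) if np.isfinite(e).all() else np.inf
        if mean / rt <= e_max:
            best = ModificationSelection(
                c=c, feasible=True, c_value=float(v),
                mean_modified_error=mean, policy=str(policy),
            )
            break
    if best is None:
        # report the floor at maximal manipulation
        c = _policy_vector(policy, 0.0, m)
        modified = u_stars + c * D
        e = gf.error_batch(modified)
        mean = float(np.mean(e)) if np.isfinite(e).all() else np.inf
        best = ModificationSelection(
            c=None, feasible=False, c_value=None,
            mean_modified_error=mean, policy=str(policy),
        )
    return best


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def adjust_block(
    block: TrialBlock,
    gf: GoalFunction,
    v_min: np.ndarray | None = None,
    e_max: float = 0.4,
    grid: SearchGrid | None = None,
    policy="uniform",
    t_mode: str = "auto",
    **proj_kwargs,
) -> AdjustmentParams:
    """Run Steps 1-3 on one prior block and return the adjustment parameters.

    Misfired/excluded trials never enter the computation.  Step 1 is skipped
    (kv = 1) for tasks without velocity-based execution variables or when
    ``v_min`` is None.
    """
    U = block.U[block.active_mask()]
    vel_cols = VELOCITY_COLS[block.task_id]
    if v_min is not None and len(vel_cols) > 0:
        kv = compute_velocity_scale(U, v_min, task_id=block.task_id)
    else:
        kv = 1.0
    U_scaled = scale_velocities(U, kv, block.task_id)
    rt = resize_target(U_scaled, gf, grid=grid, e_max=e_max, t_mode=t_mode)
    sel = select_modification_vector(
        U_scaled, gf, rt, e_max=e_max, policy=policy, **proj_kwargs
    )
    return AdjustmentParams(
        kv=kv,
        rt=rt,
        c=sel.c,
        v_min=None if v_min is None else np.asarray(v_min, float),
        e_max=e_max,
        policy=str(policy),
        feasible=sel.feasible,
        mean_modified_error=sel.mean_modified_error,
    )


def apply_adjustment(
    block: TrialBlock,
    gf: GoalFunction,
    params: AdjustmentParams,
    speed_preserving: bool = False,
    **proj_kwargs,
) -> TrialBlock:
    """Transform a block with stored parameters (velocity scale + visual
    error modification), returning a new block; inputs are not mutated."""
    out = block.copy()
    U = scale_velocities(out.U, params.kv, block.task_id)
    if params.c is not None:
        modify = (
            apply_speed_preserving_modification
            if speed_preserving
            else apply_visual_error_modification
        )
        rows = []
        for i in range(U.shape[0]):
            if not (out.excluded[i] or out.misfire[i]):
                rows.append(modify(U[i], gf, params.c, **proj_kwargs))
            else:
                rows.append(U[i])
        U = np.array(rows)
    out.U = U
    out.errors = np.full(out.n, np.nan)
    out.gross_miss = np.zeros(out.n, dtype=bool)
    return out
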