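"""Tolerance-Noise-Covariation (TNC) cost decomposition of a trial block.

Each cost is the observed set's mean error minus the mean error of an
*optimized* set obtained by manipulating one feature of the execution-space
distribution while holding the others fixed:

* **T-cost** — translate the whole cloud (centroid to every point of a
  rectangular search grid; the distribution about the centroid is
  unchanged).  Measures how much the centroid's *location* costs.
* **N-cost** — shrink the cloud toward its centroid in 1 % increments
  (scaling factors 1.00 down to 0.00); the centroid is unchanged.  Measures
  how much trial-to-trial variability costs.  A per-variable variant shrinks
  along a single execution-space axis only.
* **C-cost** — re-pair values of the second (and third) execution variable
  across trials by greedy hill-climbing swaps; marginal distributions of
  every variable are exactly preserved.  Measures how much poor covariation
  costs.

Gross-miss trials are excluded from all means (one infinite error would
poison them) and reported in the diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import GoalFunction, InputError, TrialBlock

#: Search-grid (start, step, stop) triples per task, per execution variable,
#: as used in the reference study.  Steps are oriented start -> stop.
DEFAULT_GRIDS = {
    "BA": ((0.0, 0.0033, 1.2), (0.0, 0.01, 1.5)),
    "RS": ((-2.0, 0.02, 2.0), (-1.0, 0.1, 7.0), (-11.5, 0.0656, -1.0)),
    "PB": ((0.0, -0.0296, -5.0), (0.0, -0.08, -8.0), (2.875, 0.0056, 3.458)),
}

#: N-cost scaling factors: 100 % down to 0 % in 1 % increments.
SHRINK_FACTORS = np.round(np.linspace(1.0, 0.0, 101), 2)


@dataclass(frozen=True)
class SearchGrid:
    """Rectangular lattice in execution space, one (start, step, stop)
    triple per variable."""

    axes: tuple

    def __post_init__(self) -> None:
        if len(self.axes) == 0:
            raise InputError("empty search grid")
        for start, step, stop in self.axes:
            if step == 0 or (stop - start) * step < 0:
                raise InputError(
                    f"grid axis ({start}, {step}, {stop}) cannot reach stop"
                )

    @classmethod
    def default(cls, task_id: str) -> "SearchGrid":
        if task_id not in DEFAULT_GRIDS:
            raise InputError(f"no default grid for task {task_id!r}")
        return cls(axes=DEFAULT_GRIDS[task_id])

    @classmethod
    def for_environment(cls, gf: GoalFunction, n_points: int = 81) -> "SearchGrid":
        """A grid bracketing the goal function's feasible bounds.

        Search limits are setup-specific (they depend on where the objects
        were placed); this builder re-anchors them to the constructed
        environment, the same way the reference limits were chosen from
        feasible values.
        """
        axes = []
        for lo, hi in gf.bounds:
            step = (hi - lo) / (n_points - 1)
            axes.append((float(lo), float(step), float(hi)))
        return cls(axes=tuple(axes))

    @property
    def arity(self) -> int:
        return len(self.axes)

    def axis_points(self, j: int) -> np.ndarray:
        start, step, stop = self.axes[j]
        n = int(math.floor((stop - start) / step + 1e-9)) + 1
        return start + step * np.arange(n)

    @property
    def shape(self) -> tuple:
        return tuple(len(self.axis_points(j)) for j in range(self.arity))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def steps(self) -> np.ndarray:
        return np.abs(np.array([a[1] for a in self.axes]))

    def lattice(self) -> np.ndarray:
        """All lattice points as an (n_points, m) array (C order)."""
        mesh = np.meshgrid(
            *[self.axis_points(j) for j in range(self.arity)], indexing="ij"
        )
        return np.column_stack([m.ravel() for m in mesh])

    def coarsened(self, stride: int) -> "SearchGrid":
        axes = []
        for j, (start, step, stop) in enumerate(self.axes):
            pts = self.axis_points(j)[::stride]
            axes.append((float(pts[0]), float(step * stride), float(pts[-1])))
        return SearchGrid(axes=tuple(axes))


@dataclass
class TNCResult:
    """Full TNC decomposition of one block."""

    T: float
    N: float
    C: float
    N_by_variable: dict
    U_star_T: np.ndarray
    U_star_N: np.ndarray
    U_star_C: np.ndarray
    mean_observed: float
    argmin_centroid: np.ndarray
    shrink_factor: float
    swap_count: int
    n_trials: int
    n_gross_miss: int


def _active_matrix(block_or_U, gf: GoalFunction) -> np.ndarray:
    """Trials entering TNC: finite-error, non-excluded rows."""
    if isinstance(block_or_U, TrialBlock):
        U = block_or_U.U[block_or_U.active_mask()]
    else:
        U = np.atleast_2d(np.asarray(block_or_U, dtype=float))
    if U.shape[0] < 1:
        raise InputError("no active trials")
    finite = np.isfinite(gf.error_batch(U))
    return U[finite], int((~finite).sum())


def _mean_error(gf: GoalFunction, U: np.ndarray) -> float:
    e = gf.error_batch(U)
    e = e[np.isfinite(e)]
    return float(np.mean(e)) if e.size else np.inf


def t_cost(
    block_or_U,
    gf: GoalFunction,
    grid: SearchGrid | None = None,
    mode: str = "auto",
    coarse_stride: int = 8,
    chunk_points: int = 20000,
) -> tuple[float, np.ndarray, np.ndarray]:
    """T-cost: benefit of the best rigid translation of the trial cloud.

    The centroid is shifted to every lattice point of ``grid`` (exhaustive
    ``mode="exact"``); for large grids ``mode="coarse"`` scans a stride-8
    subsample and then refines at full resolution inside the winning cell's
    neighbourhood (``mode="auto"`` picks by lattice size).  Candidate sets
    whose mean error is non-finite (e.g. everything gross-misses) are
    skipped.

    Returns ``(T, U_star, argmin_centroid)``.
    """
    if grid is None:
        grid = SearchGrid.default(gf.task_id)
    if grid.arity != gf.arity:
        raise InputError("grid arity does not match goal function")
    U, _ = _active_matrix(block_or_U, gf)
    n, m = U.shape
    centroid = U.mean(axis=0)
    centered = U - centroid
    mean_obs = _mean_error(gf, U)

    if mode == "auto":
        mode = "exact" if grid.n_points <= 500_000 else "coarse"

    def scan(points: np.ndarray) -> tuple[int, float]:
        best_i, best_mean = -1, np.inf
        for lo in range(0, points.shape[0], max(1, chunk_points // max(n, 1))):
            chunk = points[lo : lo + max(1, chunk_points // max(n, 1))]
            cand = chunk[:, None, :] + centered[None, :, :]
            e = gf.error_batch(cand.reshape(-1, m)).reshape(chunk.shape[0], n)
            with np.errstate(invalid="ignore"):
                means = np.where(
                    np.isfinite(e).all(axis=1), e.mean(axis=1), np.inf
                )
            i = int(np.argmin(means))
            if means[i] < best_mean:
                best_i, best_mean = lo + i, float(means[i])
        return best_i, best_mean

    if mode == "exact":
        pts = grid.lattice()
        best_i, best_mean = scan(pts)
        best_c = pts[best_i]
    elif mode == "coarse":
        coarse = grid.coarsened(coarse_stride)
        pts = coarse.lattice()
        ci, _ = scan(pts)
        center = pts[ci]
        # full-resolution local refinement around the coarse winner
        local_axes = []
        for j in range(m):
            ax = grid.axis_points(j)
            k = int(np.argmin(np.abs(ax - center[j])))
            local_axes.append(ax[max(0, k - coarse_stride) : k + coarse_stride + 1])
        mesh = np.meshgrid(*local_axes, indexing="ij")
        pts = np.column_stack([mm.ravel() for mm in mesh])
        best_i, best_mean = scan(pts)
        best_c = pts[best_i]
    else:
        raise InputError(f"unknown t_cost mode {mode!r}")

    if not np.isfinite(best_mean):
        raise InputError("no grid point yields a finite mean error")
    U_star = best_c + centered
    return mean_obs - best_mean, U_star, best_c


def n_cost(block_or_U, gf: GoalFunction) -> tuple[float, np.ndarray, float]:
    """N-cost: benefit of shrinking trial-to-trial variability.

    Candidate sets scale the centred cloud by factors 1.00, 0.99, ..., 0.00
    about the (fixed) centroid; the first factor (largest s) attaining the
    minimal mean error wins.  Returns ``(N, U_star, shrink_factor)``.
    """
    U, _ = _active_matrix(block_or_U, gf)
    n, m = U.shape
    centroid = U.mean(axis=0)
    centered = U - centroid
    cand = centroid + SHRINK_FACTORS[:, None, None] * centered[None, :, :]
    e = gf.error_batch(cand.reshape(-1, m)).reshape(len(SHRINK_FACTORS), n)
    with np.errstate(invalid="ignore"):
        means = np.where(np.isfinite(e).all(axis=1), e.mean(axis=1), np.inf)
    i = int(np.argmin(means))
    mean_obs = _mean_error(gf, U)
    return mean_obs - float(means[i]), cand[i], float(SHRINK_FACTORS[i])


def n_cost_by_variable(block_or_U, gf: GoalFunction, j: int) -> float:
    """Per-variable N-cost: same enumeration as :func:`n_cost` but scaling
    only execution-variable column ``j`` about the centroid."""
    U, _ = _active_matrix(block_or_U, gf)
    n, m = U.shape
    if not 0 <= j < m:
        raise InputError(f"variable index {j} out of range for arity {m}")
    centroid = U.mean(axis=0)
    cand = np.broadcast_to(U, (len(SHRINK_FACTORS), n, m)).copy()
    cand[:, :, j] = centroid[j] + SHRINK_FACTORS[:, None] * (
        U[None, :, j] - centroid[j]
    )
    e = gf.error_batch(cand.reshape(-1, m)).reshape(len(SHRINK_FACTORS), n)
    with np.errstate(invalid="ignore"):
        means = np.where(np.isfinite(e).all(axis=1), e.mean(axis=1), np.inf)
    return _mean_error(gf, U) - float(means.min())


def c_cost(
    block_or_U,
    gf: GoalFunction,
    rng: np.random.Generator | None = None,
    max_batches: int = 1000,
) -> tuple[float, np.ndarray, int]:
    """C-cost: benefit of re-pairing execution-variable values across trials.

    Greedy hill climbing: in each batch, every trial's value of the second
    (then third) execution variable is offered in exchange with every other
    trial's value; a swap is accepted iff the set's mean error strictly
    decreases.  The batch loop repeats until a batch accepts no swap.
    Column multisets — the marginal distributions — are preserved exactly.

    Iteration order is fixed (row index, partner index, variable 2 before
    variable 3) for determinism; pass ``rng`` to randomize the visit order
    per batch instead.  Returns ``(C, U_star, accepted_swap_count)``.
    """
    U, _ = _active_matrix(block_or_U, gf)
    n, m = U.shape
    mean_obs = _mean_error(gf, U)
    W = U.copy()
    if n < 2:
        return 0.0, W, 0
    errors = gf.error_batch(W)
    swap_cols = list(range(1, m))
    swaps = 0
    for _ in range(max_batches):
        accepted_in_batch = False
        rows = np.arange(n) if rng is None else rng.permutation(n)
        for i in rows:
            for j in swap_cols:
                partners = np.arange(n) if rng is None else rng.permutation(n)
                for r in partners:
                    if r == i:
                        continue
                    wi, wr = W[i, j], W[r, j]
                    if wi == wr:
                        continue
                    W[i, j], W[r, j] = wr, wi
                    ei, er = gf.error(W[i]), gf.error(W[r])
                    old = errors[i] + errors[r]
                    new = ei + er
                    if np.isfinite(new) and (not np.isfinite(old) or new < old):
                        errors[i], errors[r] = ei, er
                        swaps += 1
                        accepted_in_batch = True
                    else:
                        W[i, j], W[r, j] = wi, wr
        if not accepted_in_batch:
            break
    finite = np.isfinite(errors)
    mean_opt = float(errors[finite].mean()) if finite.any() else np.inf
    return mean_obs - mean_opt, W, swaps


def tnc(
    block_or_U,
    gf: GoalFunction,
    grid: SearchGrid | None = None,
    t_mode: str = "auto",
) -> TNCResult:
    """Full TNC decomposition of a block (T, N, C and per-variable N)."""
    U, n_miss = _active_matrix(block_or_U, gf)
    mean_obs = _mean_error(gf, U)
    T, U_T, argmin_c = t_cost(U, gf, grid=grid, mode=t_mode)
    N, U_N, s = n_cost(U, gf)
    C, U_C, swaps = c_cost(U, gf)
    names = gf.variable_names
    n_by = {names[j]: n_cost_by_variable(U, gf, j) for j in range(gf.arity)}
    return TNCResult(
        T=T,
        N=N,
        C=C,
        N_by_variable=n_by,
        U_star_T=U_T,
        U_star_N=U_N,
        U_star_C=U_C,
        mean_observed=mean_obs,
        argmin_centroid=argmin_c,
        shrink_factor=s,
        swap_count=swaps,
        n_trials=U.shape[0],
        n_gross_miss=n_miss,
    )
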