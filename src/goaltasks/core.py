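"""Shared data model and goal-function abstraction for in-place motor tasks.

A *goal function* maps one trial's execution variables ``u`` to a scalar,
nonnegative performance error via two stages: an execution mapping
``S(u, x_e1)`` that turns the movement into a change of virtual-object state,
and an environment mapping ``V(x_e2, p)`` that propagates the object through
the virtual physics to an error.  Concrete tasks live in
:mod:`goaltasks.tasks`; this module defines the conventions every other
module relies on.

Coordinate frame (right-handed):
    +y up, -z forward (away from the subject), +x toward the subject's
    dominant side; origin at the mid-stance ground point.  All internal
    quantities are SI (m, m/s, rad); degrees appear only at I/O boundaries.

Gross misses (the virtual object never reaches the target plane, or the bag
would invert) are represented as ``+inf`` error together with a boolean flag;
they are never silently dropped — filtering is the metrics module's job.
"""

from __future__ import annotations

import abc
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("goaltasks")

GRAVITY = 9.81  # m/s^2

#: Star-test reach directions at 45 degree spacing.
STAR_DIRECTIONS = ("R", "FR", "F", "FL", "L")

TASK_IDS = ("BA", "RS", "PB")

#: Lean/reach conditions as fractions of the baseline workspace limit.
CONDITION_FRACTIONS = {"near": 0.65, "mid": 0.80, "far": 0.95}

#: Number of execution variables per task.
TASK_ARITY = {"BA": 2, "RS": 3, "PB": 3}

#: Named execution-variable columns, in canonical order.
VARIABLE_NAMES = {
    "BA": ("chest_norm", "draw_norm"),
    "RS": ("vx", "vy", "vz"),
    "PB": ("vx", "vz", "d"),
}

#: Indices of velocity-based execution variables (velocity scaling applies
#: only to these; BA variables are both position/distance-based).
VELOCITY_COLS = {"BA": (), "RS": (0, 1, 2), "PB": (0, 1)}

GROSS_MISS = np.inf


class InputError(ValueError):
    """Invalid input to an operation (wrong arity, non-finite values, ...)."""


class InfeasibleError(RuntimeError):
    """A search or constraint problem has no solution in its domain."""


# ---------------------------------------------------------------------------
# subject records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Anthropometrics:
    """Subject body measurements used to scale task geometry."""

    height: float  # m
    upper_limb_length: float  # m
    handedness: str = "right"  # {"left", "right"}

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.upper_limb_length > 0):
            raise InputError("anthropometric lengths must be positive")
        if not self.upper_limb_length < self.height:
            raise InputError("upper limb length must be shorter than height")
        if self.handedness not in ("left", "right"):
            raise InputError(f"handedness must be left/right, got {self.handedness!r}")


@dataclass(frozen=True)
class WorkspaceLimits:
    """Baseline lean/reach standing star limits (5 directions at 45 deg).

    ``chest_limit`` holds maximal chest excursions, ``hand_limit`` maximal
    hand reach distances, both in metres, keyed by direction in
    :data:`STAR_DIRECTIONS`.  ``neutral_hmd_height`` is the headset height in
    neutral stance and anchors the vertical placement of virtual objects.
    """

    chest_limit: dict
    hand_limit: dict
    neutral_hmd_height: float  # m

    def __post_init__(self) -> None:
        for name, limits in (("chest", self.chest_limit), ("hand", self.hand_limit)):
            if set(limits) != set(STAR_DIRECTIONS):
                raise InputError(
                    f"{name} limits must have exactly the star directions "
                    f"{STAR_DIRECTIONS}, got {sorted(limits)}"
                )
            for d, v in limits.items():
                if not v > 0:
                    raise InputError(f"{name} limit {d} must be > 0, got {v}")
        if not self.neutral_hmd_height > 0:
            raise InputError("neutral HMD height must be > 0")

    def lateral_chest(self, handedness: str, side: str = "dominant") -> float:
        """Lateral chest limit on the dominant (or non-dominant) side."""
        right = (handedness == "right") == (side == "dominant")
        return self.chest_limit["R" if right else "L"]

    def lateral_hand(self, handedness: str, side: str = "dominant") -> float:
        right = (handedness == "right") == (side == "dominant")
        return self.hand_limit["R" if right else "L"]


def default_subject() -> tuple[Anthropometrics, WorkspaceLimits]:
    """A representative non-disabled adult subject.

    Workspace limits are cohort-mean star-test distances (normalized by
    height) scaled to a 1.75 m right-handed subject; used by the synthetic
    presets so every pipeline stage runs without any measured data.
    """
    height = 1.75
    chest_norm = {"R": 0.152, "FR": 0.128, "F": 0.081, "FL": 0.126, "L": 0.155}
    hand_norm = {"R": 0.554, "FR": 0.500, "F": 0.453, "FL": 0.498, "L": 0.553}
    anthro = Anthropometrics(height=height, upper_limb_length=0.75, handedness="right")
    limits = WorkspaceLimits(
        chest_limit={k: v * height for k, v in chest_norm.items()},
        hand_limit={k: v * height for k, v in hand_norm.items()},
        neutral_hmd_height=0.93 * height,
    )
    return anthro, limits


# ---------------------------------------------------------------------------
# object states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProjectileState:
    """Position/velocity state of the arrow (BA) or ball (RS)."""

    position: np.ndarray  # (3,) m
    velocity: np.ndarray  # (3,) m/s


@dataclass(frozen=True)
class PendulumState:
    """Angular state of the punching bag just after impact."""

    omega: float  # rad/s, initial angular speed about the pivot
    phi: float  # rad, swing azimuth (0 = dominant-lateral axis)


# ---------------------------------------------------------------------------
# trial blocks
# ---------------------------------------------------------------------------


@dataclass
class TrialBlock:
    """A block of trials: an n x m execution matrix plus per-trial flags.

    Rows of ``U`` are execution vectors in the canonical column order of
    :data:`VARIABLE_NAMES`.  Excluded/misfired trials stay in the matrix and
    are only ever *flagged*; the ``errors`` cache holds NaN until the block
    is scored.
    """

    U: np.ndarray
    task_id: str
    condition: str = "near"
    block_index: int = 1
    misfire: np.ndarray = None
    excluded: np.ndarray = None
    errors: np.ndarray = None
    gross_miss: np.ndarray = None

    def __post_init__(self) -> None:
        self.U = np.atleast_2d(np.asarray(self.U, dtype=float))
        if self.task_id not in TASK_IDS:
            raise InputError(f"unknown task_id {self.task_id!r}")
        if self.condition not in CONDITION_FRACTIONS:
            raise InputError(f"unknown condition {self.condition!r}")
        if self.block_index < 1:
            raise InputError("block_index must be >= 1")
        n, m = self.U.shape
        if n < 1:
            raise InputError("a trial block needs at least one trial")
        if m != TASK_ARITY[self.task_id]:
            raise InputError(
                f"task {self.task_id} has arity {TASK_ARITY[self.task_id]}, "
                f"got {m} columns"
            )
        if not np.all(np.isfinite(self.U)):
            raise InputError("execution variables must be finite")
        for name in ("misfire", "excluded"):
            v = getattr(self, name)
            v = np.zeros(n, dtype=bool) if v is None else np.asarray(v, dtype=bool)
            if v.shape != (n,):
                raise InputError(f"{name} flags must have shape ({n},)")
            setattr(self, name, v)
        if self.errors is None:
            self.errors = np.full(n, np.nan)
        else:
            self.errors = np.asarray(self.errors, dtype=float)
        if self.gross_miss is None:
            self.gross_miss = np.zeros(n, dtype=bool)
        else:
            self.gross_miss = np.asarray(self.gross_miss, dtype=bool)

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def arity(self) -> int:
        return self.U.shape[1]

    @property
    def variable_names(self) -> tuple:
        return VARIABLE_NAMES[self.task_id]

    def active_mask(self) -> np.ndarray:
        """Trials that enter analyses: not excluded and not misfired."""
        return ~(self.excluded | self.misfire)

    def copy(self) -> "TrialBlock":
        return TrialBlock(
            U=self.U.copy(),
            task_id=self.task_id,
            condition=self.condition,
            block_index=self.block_index,
            misfire=self.misfire.copy(),
            excluded=self.excluded.copy(),
            errors=self.errors.copy(),
            gross_miss=self.gross_miss.copy(),
        )


# ---------------------------------------------------------------------------
# goal functions
# ---------------------------------------------------------------------------


class GrossMiss(Exception):
    """Raised internally when the object cannot reach the target plane."""


class GoalFunction(abc.ABC):
    """Two-stage mapping from execution variables to scalar error.

    Subclasses provide a smooth 2-D ``residual`` (the error is its Euclidean
    norm) so that downstream code — manifold projection, TNC optimization —
    can work with a differentiable quantity; the scalar ``error`` itself is
    nonsmooth at zero.
    """

    task_id: str
    target_radius: float

    @property
    def arity(self) -> int:
        return TASK_ARITY[self.task_id]

    @property
    def variable_names(self) -> tuple:
        return VARIABLE_NAMES[self.task_id]

    @property
    @abc.abstractmethod
    def bounds(self) -> np.ndarray:
        """(m, 2) per-variable search bounds covering the feasible domain."""

    @abc.abstractmethod
    def residual(self, u: np.ndarray) -> np.ndarray:
        """2-D target-frame residual of one execution; raises GrossMiss."""

    def error(self, u: np.ndarray) -> float:
        u = self._check(u)
        try:
            return float(np.linalg.norm(self.residual(u)))
        except GrossMiss:
            return GROSS_MISS

    def error_batch(self, U: np.ndarray) -> np.ndarray:
        """Vectorized errors for an (n, m) matrix; +inf marks gross misses."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        out = np.empty(U.shape[0])
        for i, row in enumerate(U):
            out[i] = self.error(row)
        return out

    def is_gross_miss(self, u: np.ndarray) -> bool:
        return not np.isfinite(self.error(u))

    def _check(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float).ravel()
        if u.shape != (self.arity,):
            raise InputError(
                f"task {self.task_id} expects {self.arity} execution "
                f"variables, got shape {u.shape}"
            )
        if not np.all(np.isfinite(u)):
            raise InputError("execution variables must be finite")
        return u


def evaluate_goal_function(gf: GoalFunction, u: np.ndarray) -> float:
    """Scalar error of one execution; +inf (gross miss) when the object
    cannot reach the target plane.  Pure and deterministic."""
    return gf.error(u)


def score_block(gf: GoalFunction, block: TrialBlock) -> tuple[np.ndarray, float]:
    """Fill the block's error cache and return (errors, mean error).

    The mean is over active (non-excluded, non-misfire), non-gross-miss
    trials; gross misses keep their +inf error in the cache and are flagged.
    """
    if block.n < 1:
        raise InputError("empty block")
    if block.arity != gf.arity or block.task_id != gf.task_id:
        raise InputError("block and goal function disagree on task/arity")
    errors = gf.error_batch(block.U)
    block.errors = errors
    block.gross_miss = ~np.isfinite(errors)
    mask = block.active_mask() & ~block.gross_miss
    mean = float(np.mean(errors[mask])) if mask.any() else np.nan
    return errors, mean


# re-export for convenience
__all__ = [
    "GRAVITY",
    "STAR_DIRECTIONS",
    "TASK_IDS",
    "CONDITION_FRACTIONS",
    "TASK_ARITY",
    "VARIABLE_NAMES",
    "VELOCITY_COLS",
    "GROSS_MISS",
    "InputError",
    "InfeasibleError",
    "GrossMiss",
    "Anthropometrics",
    "WorkspaceLimits",
    "default_subject",
    "ProjectileState",
    "PendulumState",
    "TrialBlock",
    "GoalFunction",
    "evaluate_goal_function",
    "score_block",
]
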