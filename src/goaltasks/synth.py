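"""Seeded generators of execution-space trial blocks and pre-strike
trajectories, so every pipeline stage is testable without measured data.

Trial-to-trial scatter is modelled as a (truncated) multivariate normal
around a strategy point — the field's standard assumption of unstructured
motor noise about an intended execution; practice is modelled as geometric
decay of centroid bias and of noise across successive blocks.  Presets per
task place the strategy point near the relevant zero-error execution with
bias and spread taken from (or chosen to resemble) the reference cohort.

Everything is driven by :class:`numpy.random.Generator` (PCG64) streams
derived from one integer seed, so identical seeds give identical outputs
across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    GoalFunction,
    InputError,
    TrialBlock,
    VARIABLE_NAMES,
    default_subject,
)
from .metrics import TrajectorySeries
from .tasks import (
    PBEnvironment,
    place_objects,
    pb_zero_error_velocity,
    rs_zero_error_velocity,
)


@dataclass
class SynthSpec:
    """Specification of a synthetic trial block.

    ``centroid`` is the strategy point in execution space; ``covariance``
    the trial-to-trial noise (symmetric PSD).  ``bias_decay`` and
    ``noise_decay`` are per-block multiplicative factors applied by
    :func:`generate_learning_series` to the centroid's offset from
    ``optimal`` and to the noise SD respectively (1.0 = no practice effect).
    """

    task_id: str
    n: int
    centroid: np.ndarray
    covariance: np.ndarray
    seed: int = 0
    condition: str = "near"
    optimal: np.ndarray | None = None
    bias_decay: float = 1.0
    noise_decay: float = 1.0
    misfire_probability: float = 0.0
    domain_lo: np.ndarray | None = None
    domain_hi: np.ndarray | None = None
    # trajectory model
    sample_rate: float = 90.0  # Hz
    approach_duration: float = 0.6  # s of speed build-up before the plateau
    lateral_drift: float = 0.0  # m/s added to vx during the approach
    profile: str = "plateau"  # {"plateau", "bell"}

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).ravel()
        m = len(VARIABLE_NAMES[self.task_id])
        if self.centroid.shape != (m,):
            raise InputError(f"centroid must have {m} components")
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if self.covariance.shape != (m, m):
            raise InputError(f"covariance must be {m}x{m}")
        if not np.allclose(self.covariance, self.covariance.T):
            raise InputError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(self.covariance)
        if eig.min() < -1e-10:
            raise InputError("covariance must be positive semidefinite")
        if not 0.0 <= self.misfire_probability <= 1.0:
            raise InputError("misfire probability must be in [0, 1]")
        if self.n < 1:
            raise InputError("n must be >= 1")


def _domain_mask(spec: SynthSpec, rows: np.ndarray) -> np.ndarray:
    ok = np.ones(rows.shape[0], dtype=bool)
    if spec.domain_lo is not None:
        ok &= np.all(rows >= np.asarray(spec.domain_lo, float), axis=1)
    if spec.domain_hi is not None:
        ok &= np.all(rows <= np.asarray(spec.domain_hi, float), axis=1)
    return ok


def generate_block(spec: SynthSpec, block_index: int = 1) -> TrialBlock:
    """Draw one block from the spec's truncated multivariate normal.

    Rows falling outside the physical domain (e.g. a punching-bag hit height
    off the bag) are redrawn; an acceptance rate below 0.1 % marks the
    truncation region infeasible.  Identical specs give identical blocks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, block_index]))
    m = spec.centroid.size
    rows = np.empty((0, m))
    attempts = 0
    while rows.shape[0] < spec.n:
        draw = rng.multivariate_normal(
            spec.centroid, spec.covariance, size=max(spec.n, 16),
            method="cholesky" if np.linalg.det(spec.covariance) > 0 else "svd",
        )
        draw = draw[_domain_mask(spec, draw)]
        rows = np.vstack([rows, draw])
        attempts += 1
        if attempts > 1000:
            raise InputError("truncation region rejects nearly all samples")
    rows = rows[: spec.n]
    misfire = rng.random(spec.n) < spec.misfire_probability
    return TrialBlock(
        U=rows,
        task_id=spec.task_id,
        condition=spec.condition,
        block_index=block_index,
        misfire=misfire,
    )


def generate_learning_series(spec: SynthSpec, n_blocks: int) -> list[TrialBlock]:
    """Successive blocks with practice effects applied.

    Block ``b`` (1-based) uses centroid ``optimal + bias_decay^(b-1) *
    (centroid - optimal)`` and noise SD scaled by ``noise_decay^(b-1)``
    (covariance scaled by its square).  With both factors at 1 the blocks
    are exchangeable; bias decay drives the expected T-cost down, noise
    decay the expected N-cost.
    """
    if n_blocks < 1:
        raise InputError("n_blocks must be >= 1")
    optimal = spec.centroid if spec.optimal is None else np.asarray(
        spec.optimal, float)
    blocks = []
    for b in range(1, n_blocks + 1):
        bias = spec.bias_decay ** (b - 1)
        noise = spec.noise_decay ** (b - 1)
        sub = replace(
            spec,
            centroid=optimal + bias * (spec.centroid - optimal),
            covariance=noise**2 * spec.covariance,
        )
        blocks.append(generate_block(sub, block_index=b))
    return blocks


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def generate_trajectory(
    spec: SynthSpec, u: np.ndarray, seed_offset: int = 0
) -> TrajectorySeries:
    """Pre-strike hand trajectory ending exactly at the trial's strike
    velocity.

    The lateral (x) component holds its strike value throughout — striking
    movements build forward/vertical speed while keeping a steady lateral
    drift — so the mean lateral velocity over any analysis window equals the
    strike value exactly when ``lateral_drift`` is zero.  The default
    ``plateau`` profile ramps the remaining components up over
    ``approach_duration`` and then holds the strike velocity through the
    final second; ``bell`` replaces the hold with a smooth
    overshoot-and-settle speed bump for more lifelike histories (the strike
    sample still equals ``u`` exactly).  ``lateral_drift`` adds a
    medial/lateral bias to vx that vanishes at the strike sample.
    """
    u = np.asarray(u, dtype=float).ravel()
    if spec.task_id == "RS":
        v_strike = u.copy()
    elif spec.task_id == "PB":
        v_strike = np.array([u[0], 0.0, u[1]])
    else:
        raise InputError("trajectories are defined for RS/PB tasks")
    dt = 1.0 / spec.sample_rate
    hold = 1.0 + 2 * dt  # cover the full 1 s analysis window
    n_rise = max(2, int(round(spec.approach_duration / dt)))
    n_hold = int(round(hold / dt))
    t = dt * np.arange(n_rise + n_hold + 1)
    ramp = np.sin(0.5 * math.pi * np.arange(n_rise) / n_rise) ** 2
    if spec.profile == "plateau":
        gain = np.concatenate([ramp, np.ones(n_hold + 1)])
    elif spec.profile == "bell":
        s = np.linspace(0.0, 1.0, n_hold + 1)
        gain = np.concatenate([ramp, 1.0 + 0.3 * np.sin(math.pi * s) ** 2])
        gain[-1] = 1.0  # boundary condition: strike velocity is exact
    else:
        raise InputError(f"unknown profile {spec.profile!r}")
    velocity = gain[:, None] * v_strike[None, :]
    velocity[:, 0] = v_strike[0]  # constant lateral component
    if spec.lateral_drift:
        bump = np.concatenate([ramp, np.ones(n_hold + 1)])
        bump[-1] = 0.0
        velocity[:, 0] += spec.lateral_drift * bump
    position = np.cumsum(velocity, axis=0) * dt
    return TrajectorySeries(
        t=t, position=position, velocity=velocity, strike_index=len(t) - 1
    )


def step_trajectory(
    u_on: np.ndarray,
    u_off: np.ndarray,
    on_duration: float,
    task_id: str = "RS",
    total_duration: float = 1.5,
    sample_rate: float = 90.0,
) -> TrajectorySeries:
    """Two-level velocity profile: ``u_off`` until ``on_duration`` before the
    strike, then ``u_on`` — a constructed ground truth for on-target-time."""
    if task_id != "RS":
        raise InputError("step trajectories are built for the RS task")
    dt = 1.0 / sample_rate
    n = int(round(total_duration / dt))
    t = dt * np.arange(n + 1)
    velocity = np.tile(np.asarray(u_off, float), (n + 1, 1))
    switch = t >= t[-1] - on_duration + 1e-12
    velocity[switch] = np.asarray(u_on, float)
    position = np.cumsum(velocity, axis=0) * dt
    return TrajectorySeries(t=t, position=position, velocity=velocity,
                            strike_index=n)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def preset(task_id: str, condition: str = "near", seed: int = 0,
           environment=None) -> SynthSpec:
    """Study-condition defaults per task.

    BA: 25 trials, centroid bias (+0.076 chest, +0.104 draw) and SDs
    (0.074, 0.14) matching the reference cohort's near-lean block-1 values.
    RS: 30 trials around the zero-error 6 m/s forward strike with a small
    lateral/vertical bias.  PB: 30 trials around the desired-orientation
    punch at bag-centre height with a 5 degree lateral azimuth bias.
    """
    anthro, limits = default_subject()
    if environment is None and task_id != "BA":
        environment = place_objects(limits, anthro, task_id, condition)
    if task_id == "BA":
        from .core import CONDITION_FRACTIONS

        frac = CONDITION_FRACTIONS[condition]
        optimal = np.array([frac, 0.65])
        centroid = optimal + np.array([0.076, 0.104])
        cov = np.diag(np.array([0.074, 0.14]) ** 2)
        return SynthSpec(
            task_id="BA", n=25, centroid=centroid, covariance=cov,
            optimal=optimal, condition=condition, seed=seed,
            misfire_probability=0.04,
            domain_lo=np.zeros(2), domain_hi=np.array([1.2, 1.5]),
        )
    if task_id == "RS":
        optimal = rs_zero_error_velocity(environment, vz=-6.0)
        centroid = optimal + np.array([-0.25, 0.30, 0.40])
        cov = np.diag(np.array([0.35, 0.35, 0.60]) ** 2)
        return SynthSpec(
            task_id="RS", n=30, centroid=centroid, covariance=cov,
            optimal=optimal, condition=condition, seed=seed,
            domain_lo=np.array([-2.0, -1.0, -11.5]),
            domain_hi=np.array([2.0, 7.0, -1.0]),
        )
    if task_id == "PB":
        env: PBEnvironment = environment
        optimal = pb_zero_error_velocity(env)
        # lateral azimuth bias: rotate the punch 5 degrees toward azimuth 0
        speed = float(np.hypot(optimal[0], optimal[1]))
        phi = math.atan2(optimal[1], optimal[0]) - math.radians(5.0)
        centroid = np.array(
            [speed * math.cos(phi), speed * math.sin(phi), optimal[2]]
        )
        cov = np.diag(np.array([0.25, 0.25, 0.05]) ** 2)
        return SynthSpec(
            task_id="PB", n=30, centroid=centroid, covariance=cov,
            optimal=optimal, condition=condition, seed=seed,
            domain_lo=np.array([-8.0, -8.0, env.bag_bottom]),
            domain_hi=np.array([8.0, 8.0, env.bag_top]),
        )
    raise InputError(f"unknown task_id {task_id!r}")
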