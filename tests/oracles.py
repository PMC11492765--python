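"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form code paths: ballistic
flight is integrated numerically with fixed-step RK4, covariation
optimization is enumerated over all column permutations, rotations go
through scipy's quaternion machinery, and manifold projections are bounded
by dense-lattice scans.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def rk4_plane_hit(
    position: np.ndarray,
    velocity: np.ndarray,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    gravity: float = 9.81,
    dt: float = 1e-4,
    t_max: float = 30.0,
) -> tuple[np.ndarray, float] | None:
    """Integrate motion under gravity until the trajectory crosses the plane
    ``normal . (x - plane_point) = 0`` moving along +normal; returns the
    crossing point and time, or None if it never crosses."""
    a = np.array([0.0, -gravity, 0.0])
    p = np.asarray(position, dtype=float).copy()
    v = np.asarray(velocity, dtype=float).copy()
    n = np.asarray(plane_normal, dtype=float)
    s_prev = float(np.dot(n, p - plane_point))
    t = 0.0
    while t < t_max:
        # RK4 for state (p, v) with constant acceleration
        k1p, k1v = v, a
        k2p, k2v = v + 0.5 * dt * k1v, a
        k3p, k3v = v + 0.5 * dt * k2v, a
        k4p, k4v = v + dt * k3v, a
        p_new = p + dt / 6.0 * (k1p + 2 * k2p + 2 * k3p + k4p)
        v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        s_new = float(np.dot(n, p_new - plane_point))
        if s_prev < 0.0 <= s_new:
            # locate the crossing inside the step from the (quadratic)
            # analytic sub-step, exact for constant acceleration
            an = float(np.dot(n, a))
            vn = float(np.dot(n, v))
            coeffs = [0.5 * an, vn, s_prev]
            roots = np.roots(coeffs) if an != 0 else np.array([-s_prev / vn])
            roots = roots[np.isreal(roots)].real
            tau = min(r for r in roots if -1e-12 <= r <= dt + 1e-9)
            hit = p + v * tau + 0.5 * a * tau**2
            return hit, t + tau
        p, v, s_prev = p_new, v_new, s_new
        t += dt
    return None


def exhaustive_c_cost(U: np.ndarray, error_batch) -> float:
    """Global covariation optimum by brute force: the first column stays
    fixed, every other column is permuted over all n! orders independently
    is intractable, so this handles the 2-variable case (one permuted
    column) exactly."""
    U = np.asarray(U, dtype=float)
    n, m = U.shape
    assert m == 2, "factorial oracle is for 2-variable tasks"
    mean_obs = float(np.mean(error_batch(U)))
    best = np.inf
    col = U[:, 1]
    for perm in itertools.permutations(range(n)):
        W = np.column_stack([U[:, 0], col[list(perm)]])
        mean = float(np.mean(error_batch(W)))
        if mean < best:
            best = mean
    return mean_obs - best


def rotation_angle_between_axes(a: np.ndarray, b: np.ndarray) -> float:
    """Magnitude (degrees) of the minimal rotation mapping axis b to axis a,
    computed through scipy's quaternion solver."""
    rot, _ = Rotation.align_vectors(np.atleast_2d(a), np.atleast_2d(b))
    return float(np.degrees(rot.magnitude()))


def lattice_projection_bound(
    u: np.ndarray, error_batch, bounds: np.ndarray, n: int = 41,
    tol: float = 1e-3,
) -> float:
    """Distance from u to the nearest near-zero-error lattice point: an
    upper bound (up to lattice spacing) on the true manifold distance."""
    grids = [np.linspace(lo, hi, n) for lo, hi in bounds]
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.column_stack([mm.ravel() for mm in mesh])
    e = error_batch(pts)
    near = pts[np.isfinite(e) & (e <= tol)]
    if near.size == 0:
        return np.inf
    return float(np.min(np.linalg.norm(near - np.asarray(u, float), axis=1)))
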