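"""Sprint motion model and minimum arrival times.

A player is modelled as a point mass driven by a constant-magnitude force in a
chosen direction n and a viscous drag proportional to velocity:

    m x'' = F n - k x'

Its closed-form trajectory from initial position ``x0`` and velocity ``v0`` is

    x(t) = x0 + (1 - exp(-alpha t)) / alpha * v0
              + v_max * (t - (1 - exp(-alpha t)) / alpha) * n,

where ``v_max = F/m`` is the terminal sprint speed and ``alpha = k/m`` the
inverse relaxation time. At any time t the set of positions reachable over all
unit directions n is a circle: a drift centre carried by the decaying initial
velocity plus an isotropic sprint radius. The minimum arrival time to a target
is therefore the first time the growing reach circle touches the target, found
as the first sign change of

    g(t) = || target - centre(t) || - radius(t)

on a coarse time grid, refined by bisection. g need not be monotone when v0
points away from the target, so the *first* crossing matters; a bracketing
solver started from an arbitrary interval could skip it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .errors import NumericalError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .tracking_io import PlayerState

#: default terminal sprint speed (m/s) and relaxation rate (1/s); typical
#: sprint values that vary little between professional players
DEFAULT_V_MAX = 7.8
DEFAULT_ALPHA = 1.3

#: recorded speeds above this (m/s) are treated as suspect tracking noise
SPEED_WARN = 12.0

#: players closer to the target than this (m) are already there
POSITION_TOL = 1e-6


@dataclass(frozen=True)
class MotionParams:
    """Terminal speed ``v_max`` (m/s) and relaxation rate ``alpha`` (1/s)."""

    v_max: float = DEFAULT_V_MAX
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not (self.v_max > 0):
            raise ValidationError(f"v_max must be positive, got {self.v_max}")
        if not (self.alpha > 0):
            raise ValidationError(f"alpha must be positive, got {self.alpha}")


@dataclass(frozen=True)
class ReachState:
    """Reachable set at one instant: all points ``center + radius * n``, |n|=1."""

    center: np.ndarray  # (2,) m
    radius: float  # m


def _drift(alpha: float, t):
    """(1 - exp(-alpha t)) / alpha — the integrated decay of the initial velocity."""
    return -np.expm1(-alpha * np.asarray(t, dtype=float)) / alpha


def position_at(state: "PlayerState", params: MotionParams, n, t: float) -> np.ndarray:
    """Evaluate the closed-form trajectory for sprint direction ``n`` at time ``t``."""
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-9:
        raise ValidationError(f"direction must be a unit vector, |n|={np.linalg.norm(n)}")
    if t < 0:
        raise ValidationError(f"time must be non-negative, got {t}")
    d = _drift(params.alpha, t)
    return state.position + d * state.velocity + params.v_max * (t - d) * n


def reach_state(state: "PlayerState", params: MotionParams, t: float) -> ReachState:
    """Drift centre and sprint radius of the reachable circle at time ``t``."""
    if t < 0:
        raise ValidationError(f"time must be non-negative, got {t}")
    d = _drift(params.alpha, t)
    center = state.position + d * state.velocity
    radius = params.v_max * (t - d)
    return ReachState(center=center, radius=float(radius))


def arrival_time_field(
    x0,
    v0,
    params: MotionParams,
    targets,
    *,
    coarse_dt: float = 0.01,
    t_max: float = 60.0,
    tol: float = 1e-6,
) -> np.ndarray:
    """Minimum arrival times of one player to an array of targets.

    Parameters
    ----------
    x0, v0
        Initial position and velocity, shape (2,).
    targets
        Target locations, shape (n, 2).
    coarse_dt
        Scan step (s) used to bracket the first crossing of g(t).
    t_max
        Hard cap (s); failing to cross before it signals absurd inputs.
    tol
        Bisection tolerance (s) on the refined root.

    Returns
    -------
    numpy.ndarray of shape (n,), seconds.
    """
    x0 = np.asarray(x0, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if not np.all(np.isfinite(targets)):
        raise ValidationError("targets must be finite")
    if not (np.all(np.isfinite(x0)) and np.all(np.isfinite(v0))):
        raise ValidationError("player state must be finite")
    speed = float(np.linalg.norm(v0))
    if speed > SPEED_WARN:
        warnings.warn(
            f"initial speed {speed:.1f} m/s exceeds {SPEED_WARN} m/s; "
            "treating as valid but the tracking data look noisy",
            stacklevel=2,
        )

    alpha, v_max = params.alpha, params.v_max
    d0 = np.linalg.norm(targets - x0, axis=1)
    tau = np.zeros(len(targets))
    todo = d0 >= POSITION_TOL
    if not np.any(todo):
        return tau

    # Guaranteed upper bound on the first crossing: the drift centre never
    # strays more than |v0|/alpha from x0, and radius(t) >= v_max*t - v_max/alpha.
    bound = (d0[todo].max() + speed / alpha) / v_max + 1.0 / alpha + 2.0 * coarse_dt
    bound = min(bound, t_max)
    t_grid = np.arange(0.0, bound + coarse_dt, coarse_dt)
    drift = _drift(alpha, t_grid)
    centers = x0 + drift[:, None] * v0  # (T, 2)
    radii = v_max * (t_grid - drift)  # (T,)

    pts = targets[todo]
    n_pts = len(pts)
    first_idx = np.empty(n_pts, dtype=np.intp)
    crossed = np.zeros(n_pts, dtype=bool)
    chunk = max(1, int(4e6 // max(len(t_grid), 1)))
    for lo in range(0, n_pts, chunk):
        sl = slice(lo, min(lo + chunk, n_pts))
        diff = pts[sl, None, :] - centers[None, :, :]  # (c, T, 2)
        g = np.sqrt(np.einsum("ctk,ctk->ct", diff, diff)) - radii
        hit = g <= 0.0
        crossed[sl] = hit.any(axis=1)
        first_idx[sl] = hit.argmax(axis=1)
    if not crossed.all():
        raise NumericalError(
            f"no arrival before t_max={t_max} s for {int((~crossed).sum())} target(s); "
            "check player state and target coordinates"
        )

    # Refine each bracket [t[i-1], t[i]] by bisection.  g(0) = d0 > 0 here, so
    # the first hit index is always >= 1.
    lo_t = t_grid[first_idx - 1]
    hi_t = t_grid[first_idx]
    n_iter = int(np.ceil(np.log2(coarse_dt / tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo_t + hi_t)
        d_mid = _drift(alpha, mid)
        c_mid = x0 + d_mid[:, None] * v0
        g_mid = np.linalg.norm(pts - c_mid, axis=1) - v_max * (mid - d_mid)
        neg = g_mid <= 0.0
        hi_t = np.where(neg, mid, hi_t)
        lo_t = np.where(neg, lo_t, mid)
    tau[todo] = 0.5 * (lo_t + hi_t)
    return tau


def min_arrival_time(
    state: "PlayerState",
    params: MotionParams,
    target,
    *,
    coarse_dt: float = 0.01,
    t_max: float = 60.0,
    tol: float = 1e-6,
) -> float:
    """Smallest t >= 0 at which the player's reach circle contains ``target``."""
    out = arrival_time_field(
        state.position,
        state.velocity,
        params,
        np.asarray(target, dtype=float)[None, :],
        coarse_dt=coarse_dt,
        t_max=t_max,
        tol=tol,
    )
    return float(out[0])
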