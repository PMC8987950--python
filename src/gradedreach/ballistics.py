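"""Inverse ballistic launch solvers and drag-free flight simulation.

Launched objects (dodgeballs, jumping fish) are point masses under gravity
alone, so every flight is a parabola.  Two inverse problems are solved:

``solve_fixed_speed_angle``
    The dodgeball case.  Launch speed ``v0`` is held constant and the launch
    angle α is chosen so the parabola passes through the target.  Of the two
    real roots the *low arc* (smaller α) is returned — incoming balls fly a
    flat, fast trajectory toward the player.

``solve_fixed_apex``
    The fish case.  Both speed and angle are chosen so the flight reaches a
    prescribed apex height ``H`` and intercepts the target on the *descending
    limb* — the fish jumps in a high slow arc and would land in the water
    short of the player if not caught.

All geometry is planar (midsagittal): x anterior, z up, in meters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .targets import TargetPoint

__all__ = [
    "GRAVITY",
    "LaunchSite",
    "LaunchSolution",
    "Trajectory",
    "UnreachableTargetError",
    "solve_fixed_speed_angle",
    "solve_fixed_apex",
    "simulate_flight",
    "apex_height",
]

#: Standard gravity, m/s².
GRAVITY = 9.81

#: Launch-site defaults (configurable; nothing downstream depends on them).
DODGEBALL_SITE_X, DODGEBALL_SITE_Z = 3.0, 1.6
FISH_SITE_X, FISH_SITE_Z = 2.5, 0.0
DODGEBALL_SPEED = 8.0  # m/s
FISH_APEX = 2.0  # m


class UnreachableTargetError(ValueError):
    """The requested geometry admits no real launch solution."""


@dataclass(frozen=True)
class LaunchSite:
    """Projectile release point (m) in the feet-midpoint frame."""

    x0: float
    z0: float

    def __post_init__(self) -> None:
        if self.z0 < 0.0:
            raise ValueError(f"release height must be non-negative, got {self.z0}")


@dataclass(frozen=True)
class LaunchSolution:
    """Launch parameters whose parabolic flight intercepts the target."""

    v0: float  # launch speed, m/s
    alpha: float  # launch angle above horizontal, degrees
    vx0: float  # signed horizontal velocity, m/s
    vz0: float  # signed vertical velocity, m/s
    t_flight: float  # release to intended intercept, s
    mode: Literal["fixed_speed_low_arc", "fixed_apex_descending"]


@dataclass(frozen=True)
class Trajectory:
    """Closed-form samples of a parabolic flight."""

    t: np.ndarray  # s, from release
    x: np.ndarray  # m
    z: np.ndarray  # m
    dt: float


def solve_fixed_speed_angle(
    site: LaunchSite,
    target: TargetPoint,
    v0: float = DODGEBALL_SPEED,
    g: float = GRAVITY,
) -> LaunchSolution:
    """Solve the launch angle for a fixed launch speed (low-arc root).

    With horizontal range ``R = |x_t − x0|`` and rise ``Δz = z_t − z0``, the
    angle satisfies ``Δz = R·tanα − g·R²/(2 v0² cos²α)``, a quadratic in
    ``tanα``.  The smaller-α root (flat trajectory) is returned.

    Raises
    ------
    UnreachableTargetError
        If the discriminant is negative (``v0`` too small for the geometry).
    ValueError
        If the horizontal range is zero or ``v0 ≤ 0``.
    """
    if v0 <= 0.0:
        raise ValueError(f"launch speed must be positive, got {v0}")
    if g <= 0.0:
        raise ValueError(f"gravity must be positive, got {g}")
    R = target.anterior - site.x0
    if R == 0.0:
        raise ValueError("degenerate geometry: zero horizontal range")
    dz = target.vertical - site.z0

    # tan-alpha quadratic: (gR²/2v0²)·u² − R·u + (Δz + gR²/2v0²) = 0
    # with u = tanα and R the *signed* range; use |R| and restore sign via vx0.
    Rm = abs(R)
    k = g * Rm * Rm / (2.0 * v0 * v0)
    disc = Rm * Rm - 4.0 * k * (dz + k)
    if disc < 0.0:
        raise UnreachableTargetError(
            f"target unreachable at v0={v0} m/s (discriminant {disc:.3e} < 0)"
        )
    u_low = (Rm - math.sqrt(disc)) / (2.0 * k)  # smaller tanα → flat arc
    alpha = math.degrees(math.atan(u_low))
    vx = v0 * math.cos(math.atan(u_low)) * math.copysign(1.0, R)
    vz = v0 * math.sin(math.atan(u_low))
    t_flight = Rm / (v0 * math.cos(math.atan(u_low)))
    return LaunchSolution(
        v0=v0, alpha=alpha, vx0=vx, vz0=vz, t_flight=t_flight,
        mode="fixed_speed_low_arc",
    )


def solve_fixed_apex(
    site: LaunchSite,
    target: TargetPoint,
    H: float = FISH_APEX,
    g: float = GRAVITY,
) -> LaunchSolution:
    """Solve speed and angle so the flight peaks at ``H`` and intercepts on
    the descending limb.

    ``vz0 = sqrt(2g(H − z0))``; time of flight is time-to-apex plus the
    descent to the target height, ``t = vz0/g + sqrt(2(H − z_t)/g)``; the
    horizontal velocity then follows from the range.

    Raises
    ------
    UnreachableTargetError
        If ``H`` is not strictly above both the release and intercept heights
        (the descending-limb intercept would be degenerate).
    """
    if g <= 0.0:
        raise ValueError(f"gravity must be positive, got {g}")
    if H <= site.z0 or H <= target.vertical:
        raise UnreachableTargetError(
            f"apex H={H} m must exceed both release z0={site.z0} m "
            f"and intercept z={target.vertical} m"
        )
    R = target.anterior - site.x0
    if R == 0.0:
        raise ValueError("degenerate geometry: zero horizontal range")
    vz0 = math.sqrt(2.0 * g * (H - site.z0))
    t_flight = vz0 / g + math.sqrt(2.0 * (H - target.vertical) / g)
    vx0 = R / t_flight
    v0 = math.hypot(vx0, vz0)
    alpha = math.degrees(math.atan2(vz0, abs(vx0)))
    return LaunchSolution(
        v0=v0, alpha=alpha, vx0=vx0, vz0=vz0, t_flight=t_flight,
        mode="fixed_apex_descending",
    )


def apex_height(site: LaunchSite, sol: LaunchSolution, g: float = GRAVITY) -> float:
    """Maximum height of the closed-form flight path on ``[0, t_flight]``.

    Evaluated analytically (the apex rarely falls on a sample grid): the
    vertex ``z0 + vz0²/2g`` when the apex time lies inside the flight,
    otherwise the higher endpoint.
    """
    t_apex = sol.vz0 / g
    if 0.0 <= t_apex <= sol.t_flight:
        return site.z0 + sol.vz0 * sol.vz0 / (2.0 * g)
    z_end = site.z0 + sol.vz0 * sol.t_flight - 0.5 * g * sol.t_flight**2
    return max(site.z0, z_end)


def simulate_flight(
    site: LaunchSite,
    sol: LaunchSolution,
    g: float = GRAVITY,
    dt: float = 0.01,
) -> Trajectory:
    """Sample the closed-form parabola on ``[0, t_flight]``.

    The final sample lands exactly at ``t_flight`` so the intended intercept
    is always in the sample set.
    """
    if dt <= 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    n = int(math.floor(sol.t_flight / dt))
    t = np.arange(n + 1) * dt
    if t[-1] < sol.t_flight:
        t = np.append(t, sol.t_flight)
    x = site.x0 + sol.vx0 * t
    z = site.z0 + sol.vz0 * t - 0.5 * g * t * t
    return Trajectory(t=t, x=x, z=z, dt=dt)
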