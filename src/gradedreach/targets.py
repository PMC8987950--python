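"""Anthropometry-scaled target placement for graded trunk-flexion reaching.

The reaching task presents four contact points in the midsagittal plane that
would require exactly 15°, 30°, 45°, and 60° of trunk flexion to reach *if the
participant moved only at the trunk*.  Targets are derived per participant
from three segment lengths: hip height (floor to hip pivot), trunk length
(hip pivot to shoulder), and arm length (shoulder to hand).

Coordinate frame: origin at the midpoint of the feet on the floor, +x anterior,
+z up.  The hip pivot sits on the vertical line through the origin (upright
stance calibration).  In the reference posture the trunk is vertical and the
arm points horizontally forward, so the hand is at ``(L_a, h_hip + L_t)``.
Rotating trunk+arm rigidly about the hip pivot by the flexion angle θ places
the hand at::

    anterior = L_t·sin(θ) + L_a·cos(θ)
    vertical = h_hip + L_t·cos(θ) − L_a·sin(θ)

The hand-to-pivot distance ``sqrt(L_t² + L_a²)`` is independent of θ, and the
vertical coordinate decreases strictly with θ on (0°, 90°), so the four
targets form a descending arc in front of the participant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "DEFAULT_THETAS",
    "Anthropometry",
    "TargetPoint",
    "TargetSet",
    "compute_target",
    "compute_target_set",
]

#: Trunk-flexion angles (degrees) used by every game in the suite.
DEFAULT_THETAS: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class Anthropometry:
    """Participant segment lengths in meters.

    Attributes
    ----------
    hip_height : float
        Floor to hip pivot.
    trunk_length : float
        Hip pivot to shoulder.
    arm_length : float
        Shoulder to hand.
    """

    hip_height: float
    trunk_length: float
    arm_length: float

    def __post_init__(self) -> None:
        for name in ("hip_height", "trunk_length", "arm_length"):
            value = getattr(self, name)
            if not (value > 0.0) or not math.isfinite(value):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def reach_radius(self) -> float:
        """Hand-to-hip-pivot distance in the rigid posture, ``sqrt(L_t²+L_a²)``."""
        return math.hypot(self.trunk_length, self.arm_length)

    @property
    def hip_pivot(self) -> tuple[float, float]:
        """(x, z) of the hip pivot in the feet-midpoint frame."""
        return (0.0, self.hip_height)


@dataclass(frozen=True)
class TargetPoint:
    """An intended impact location and the trunk-flexion angle it encodes."""

    theta: float  # degrees of isolated trunk flexion
    anterior: float  # m, +x forward of the feet midpoint
    vertical: float  # m, +z above the floor


@dataclass(frozen=True)
class TargetSet:
    """Ordered targets (one per θ) plus the anthropometry that produced them."""

    points: tuple[TargetPoint, ...]
    anthropometry: Anthropometry
    thetas: tuple[float, ...] = field(default=DEFAULT_THETAS)

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, i: int) -> TargetPoint:
        return self.points[i]

    def by_theta(self, theta: float) -> TargetPoint:
        for p in self.points:
            if math.isclose(p.theta, theta):
                return p
        raise KeyError(f"no target at theta={theta}")


def compute_target(anthro: Anthropometry, theta: float) -> TargetPoint:
    """Hand position after rotating trunk+arm rigidly about the hip by ``theta``.

    Parameters
    ----------
    anthro : Anthropometry
        Segment lengths (m).
    theta : float
        Trunk-flexion angle in degrees, ``0 ≤ theta < 90``.

    Returns
    -------
    TargetPoint
        Anterior/vertical coordinates (m) in the feet-midpoint frame.

    Raises
    ------
    ValueError
        If ``theta`` lies outside ``[0, 90)``.
    """
    if not (0.0 <= theta < 90.0):
        raise ValueError(f"theta must lie in [0, 90) degrees, got {theta}")
    rad = math.radians(theta)
    lt, la = anthro.trunk_length, anthro.arm_length
    anterior = lt * math.sin(rad) + la * math.cos(rad)
    vertical = anthro.hip_height + lt * math.cos(rad) - la * math.sin(rad)
    return TargetPoint(theta=theta, anterior=anterior, vertical=vertical)


def compute_target_set(
    anthro: Anthropometry, thetas: Sequence[float] = DEFAULT_THETAS
) -> TargetSet:
    """Compute one target per flexion angle.

    ``thetas`` must be strictly increasing within ``[0, 90)``; the returned
    targets then descend strictly in height (d vertical/dθ = −L_t sinθ −
    L_a cosθ < 0 on the open interval).
    """
    thetas = tuple(float(t) for t in thetas)
    if not thetas:
        raise ValueError("thetas must be non-empty")
    if any(b <= a for a, b in zip(thetas, thetas[1:])):
        raise ValueError(f"thetas must be strictly increasing, got {thetas}")
    points = tuple(compute_target(anthro, t) for t in thetas)
    return TargetSet(points=points, anthropometry=anthro, thetas=thetas)
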