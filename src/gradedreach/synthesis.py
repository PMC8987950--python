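"""Synthetic 100 Hz trial recordings emulating cue→react→reach mocap data.

No cohort mocap data ship with the package; this module generates recordings
with known ground truth so the whole downstream pipeline (filtering, event
windowing, outcome extraction, statistics) can be exercised and validated.

The participant is a planar two-link chain in the midsagittal plane: a trunk
link (hip pivot → shoulder) and an arm link (shoulder → hand).  Reaching a
point decomposes the required trunk reorientation φ into a lumbar component
(``lumbar_share · φ``) and a lumped hip/lower-limb remainder, mirroring the
kinematic redundancy that lets real participants trade trunk motion against
hip and leg motion.  Angles follow the minimum-jerk profile

    s(τ) = 10τ³ − 15τ⁴ + 6τ⁵,   τ = (t − t_onset)/T,

whose peak rate is ``1.875·A/T`` for amplitude ``A`` and duration ``T``.

Game pacing enters through two channels: a per-game speed gain that shortens
the preferred movement time, and the time the flight itself allows (launch
cue leads the release, and the intercept must be met on time).  Dodgeality
additionally carries an anticipatory extra lumbar flexion at the *higher*
targets — players start ducking downward before they resolve the incoming
flat, fast ball — which the hip component compensates so the hand still meets
the ball.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np

from .ballistics import (
    GRAVITY,
    LaunchSite,
    Trajectory,
    simulate_flight,
    solve_fixed_apex,
    solve_fixed_speed_angle,
)
from .protocol import TrialPlanItem, plan_session
from .targets import DEFAULT_THETAS, Anthropometry, TargetPoint, compute_target

__all__ = [
    "GameParams",
    "ParticipantModel",
    "InterceptPolicy",
    "TrialRecording",
    "minimum_jerk",
    "two_link_ik",
    "choose_intercept",
    "synthesize_trial",
    "synthesize_cohort",
]

#: Floor on achievable movement time, s — even rushed reaches take this long.
MIN_MOVEMENT_TIME = 0.2


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile ``10τ³ − 15τ⁴ + 6τ⁵`` on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


@dataclass(frozen=True)
class GameParams:
    """Suite-level gameplay configuration shared by all participants."""

    thetas: tuple[float, ...] = DEFAULT_THETAS
    gravity: float = GRAVITY
    dodgeball_speed: float = 8.0  # m/s, constant launch speed
    dodgeball_site: tuple[float, float] = (3.0, 1.6)  # thrower hand, m
    fish_apex: float = 2.0  # m, prescribed apex height H
    fish_site: tuple[float, float] = (2.5, 0.0)  # water surface, m
    #: Cue precedes release: the opponent winds up / the fish swims in first.
    cue_lead: Mapping[str, float] = field(
        default_factory=lambda: {"fishality": 1.0, "dodgeality": 0.4}
    )
    fs: float = 100.0  # Hz
    contact_radius: float = 0.05  # m, hand-to-projectile catch radius
    target_contact_radius: float = 0.01  # m, static-target pass-through radius
    #: Extra anticipatory lumbar flexion (deg) for Dodgeality at the highest
    #: target, tapering linearly to zero at the lowest.
    anticipation_deg: float = 12.0
    #: Where along the flight the player intercepts: both launch games default
    #: to blocking/catching near the intended intercept at the body; the
    #: earliest-reachable alternative models lunging at full extension.
    intercept_policy: Mapping[str, str] = field(
        default_factory=lambda: {
            "dodgeality": "closest_to_intended",
            "fishality": "closest_to_intended",
        }
    )
    pre_cue_s: float = 0.5  # quiet stance before the cue
    hold_s: float = 2.0  # Reachality in-target hold
    post_s: float = 0.5  # recording continues after the event


@dataclass(frozen=True)
class ParticipantModel:
    """Traits governing how one synthetic participant moves.

    ``lumbar_share`` is the fraction of the required trunk reorientation
    produced at the lumbar joint (the rest is lumped hip/lower-limb motion);
    ``speed_gain`` divides the preferred movement time per game; ``noise_sd``
    is additive Gaussian measurement noise on recorded angles, degrees.
    """

    anthro: Anthropometry
    lumbar_share: float = 0.7
    reaction_time: float = 0.25  # s
    movement_time: float = 1.1  # s, preferred (self-paced) duration
    speed_gain: Mapping[str, float] = field(
        default_factory=lambda: {"reachality": 1.0, "fishality": 1.15, "dodgeality": 2.2}
    )
    noise_sd: float = 0.3  # degrees

    def __post_init__(self) -> None:
        if not (0.0 <= self.lumbar_share <= 1.0):
            raise ValueError(f"lumbar_share must be in [0, 1], got {self.lumbar_share}")
        if self.movement_time <= 0.0:
            raise ValueError("movement_time must be positive")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class InterceptPolicy:
    """How the participant picks a catch point along the flight.

    ``reach_envelope`` bounds the hand-to-shoulder distance; since the
    shoulder rides a circle of radius ``trunk_length`` about the hip pivot, a
    point p is reachable iff ``| |p − hip| − trunk_length | ≤ reach_envelope``.
    """

    reach_envelope: float
    policy: Literal["earliest_reachable", "closest_to_intended"] = "earliest_reachable"

    @classmethod
    def for_participant(
        cls, participant: "ParticipantModel",
        policy: Literal["earliest_reachable", "closest_to_intended"] = "earliest_reachable",
    ) -> "InterceptPolicy":
        return cls(reach_envelope=participant.anthro.arm_length, policy=policy)

    def validate(self, anthro: Anthropometry) -> None:
        if self.reach_envelope > anthro.arm_length * 1.05:
            raise ValueError("reach_envelope exceeds 1.05 × arm length")


@dataclass
class TrialRecording:
    """One trial: uniformly sampled angles/hand path plus event markers."""

    t: np.ndarray  # s
    lumbar_flexion: np.ndarray  # degrees, thorax relative to pelvis (sagittal)
    hand_x: np.ndarray  # m, anterior
    hand_z: np.ndarray  # m, vertical
    cue_time: float  # s: movement may begin (target appears / wind-up / fish swims)
    contact_time: Optional[float]  # s, or None for a missed trial
    game: str
    theta: Optional[float]
    hand: Optional[str]
    event_kind: str = "reach"
    participant: str = ""
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.contact_time is not None and not self.cue_time < self.contact_time:
            raise ValueError("cue_time must precede contact_time")


def two_link_ik(
    anthro: Anthropometry, point: tuple[float, float]
) -> Optional[tuple[float, float]]:
    """Trunk flexion φ and arm elevation ψ (degrees) placing the hand at ``point``.

    Reference posture: trunk vertical, arm horizontal forward, so the hand
    sits at ``(L_a, h_hip + L_t)`` and ψ is measured relative to the
    trunk-perpendicular arm.  Returns ``None`` when the point lies outside
    the annulus ``[|L_t − L_a|, L_t + L_a]`` around the hip pivot.
    """
    lt, la = anthro.trunk_length, anthro.arm_length
    px = point[0]
    pz = point[1] - anthro.hip_height
    r = math.hypot(px, pz)
    if r > lt + la + 1e-12 or r < abs(lt - la) - 1e-12:
        return None
    c = (r * r - lt * lt - la * la) / (2.0 * lt * la)
    gamma = math.acos(min(1.0, max(-1.0, c)))  # inter-link angle, [0, π]
    psi = math.degrees(gamma) - 90.0
    beta = math.atan2(px, pz)  # point direction from vertical
    delta = math.atan2(la * math.sin(gamma), lt + la * math.cos(gamma))
    phi = math.degrees(beta - delta)
    return phi, psi


def _forward_hand(
    anthro: Anthropometry, phi_deg: np.ndarray, psi_deg: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hand position from trunk flexion φ and arm elevation ψ (degrees)."""
    phi = np.radians(phi_deg)
    ap = np.radians(phi_deg + psi_deg)
    x = anthro.trunk_length * np.sin(phi) + anthro.arm_length * np.cos(ap)
    z = anthro.hip_height + anthro.trunk_length * np.cos(phi) - anthro.arm_length * np.sin(ap)
    return x, z


def choose_intercept(
    traj: Trajectory,
    participant: ParticipantModel,
    policy: InterceptPolicy,
    min_time: float = 0.0,
    intended: Optional[TargetPoint] = None,
) -> Optional[tuple[float, tuple[float, float]]]:
    """Pick the catch sample along a flight, or ``None`` for a miss.

    ``earliest_reachable`` returns the first sample at or after ``min_time``
    (trajectory clock) inside the reach annulus; ``closest_to_intended``
    returns the reachable sample nearest the intended target.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    policy.validate(participant.anthro)
    hx, hz = participant.anthro.hip_pivot
    d = np.hypot(traj.x - hx, traj.z - hz)
    reachable = (
        (np.abs(d - participant.anthro.trunk_length) <= policy.reach_envelope)
        & (traj.t >= min_time - 1e-12)
        & (traj.z >= 0.0)
    )
    idx = np.flatnonzero(reachable)
    if idx.size == 0:
        return None
    if policy.policy == "earliest_reachable":
        i = idx[0]
    elif policy.policy == "closest_to_intended":
        if intended is None:
            raise ValueError("closest_to_intended requires the intended target")
        miss = np.hypot(traj.x[idx] - intended.anterior, traj.z[idx] - intended.vertical)
        i = idx[int(np.argmin(miss))]
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown policy {policy.policy!r}")
    return float(traj.t[i]), (float(traj.x[i]), float(traj.z[i]))


def _snap(t: float, fs: float) -> float:
    return round(t * fs) / fs


def _anticipation(params: GameParams, game: str, theta: float) -> float:
    if game != "dodgeality" or params.anticipation_deg == 0.0:
        return 0.0
    lo, hi = min(params.thetas), max(params.thetas)
    frac = (hi - theta) / (hi - lo) if hi > lo else 0.0
    return params.anticipation_deg * max(0.0, frac)


def synthesize_trial(
    plan_item: TrialPlanItem,
    participant: ParticipantModel,
    target_or_traj: Union[TargetPoint, tuple[TargetPoint, Trajectory], None],
    seed: int,
    params: GameParams = GameParams(),
    policy: Optional[InterceptPolicy] = None,
) -> TrialRecording:
    """Generate one trial recording for a planned reach or launch.

    ``target_or_traj`` is the TargetPoint for Reachality, a
    ``(TargetPoint, Trajectory)`` pair for the launch games, and ``None`` for
    duck events (which yield a quiet-stance placeholder recording — ducking
    kinematics are out of analysis scope).  A fixed seed gives a bit-identical
    recording.
    """
    rng = np.random.default_rng(seed)
    fs, dt = params.fs, 1.0 / params.fs
    anthro = participant.anthro
    cue = _snap(params.pre_cue_s, fs)
    game = plan_item.game

    if plan_item.event_kind == "duck":
        n = int(round(2.0 * fs)) + 1
        t = np.arange(n) * dt
        lumbar = rng.normal(0.0, participant.noise_sd, n)
        hand_x = np.full(n, anthro.arm_length)
        hand_z = np.full(n, anthro.hip_height + anthro.trunk_length)
        return TrialRecording(
            t=t, lumbar_flexion=lumbar, hand_x=hand_x, hand_z=hand_z,
            cue_time=cue, contact_time=None, game=game, theta=None,
            hand=plan_item.hand, event_kind="duck", fs=fs,
        )

    if target_or_traj is None:
        raise ValueError("reach/launch trials need a target or (target, trajectory)")

    reaction = max(0.1, participant.reaction_time + rng.normal(0.0, 0.02))
    start = cue + reaction
    preferred_mt = participant.movement_time / participant.speed_gain.get(game, 1.0)

    traj: Optional[Trajectory] = None
    if isinstance(target_or_traj, TargetPoint):
        target = target_or_traj
        intercept_point: Optional[tuple[float, float]] = (target.anterior, target.vertical)
        t_intercept: Optional[float] = None  # static target: no flight clock
        movement_time = preferred_mt
    else:
        target, traj = target_or_traj
        pol = policy or InterceptPolicy.for_participant(
            participant, params.intercept_policy.get(game, "earliest_reachable")  # type: ignore[arg-type]
        )
        lead = params.cue_lead.get(game, 0.0)
        found = choose_intercept(
            traj, participant, pol,
            min_time=max(0.0, reaction - lead), intended=target,
        )
        if found is None:
            intercept_point = None
            t_intercept = None
            movement_time = preferred_mt
        else:
            # Snap the intercept onto the recording grid (flooring, so the
            # ball is still in flight there) and aim at the ball's position
            # at that instant.
            t_star = found[0]
            t_k = math.floor(t_star * fs + 1e-9) / fs
            intercept_point = (
                float(np.interp(t_k, traj.t, traj.x)),
                float(np.interp(t_k, traj.t, traj.z)),
            )
            t_intercept = _snap(cue + lead + t_k, fs)
            available = t_intercept - start
            movement_time = min(preferred_mt, available)
        if movement_time < MIN_MOVEMENT_TIME:
            movement_time = MIN_MOVEMENT_TIME  # rushed trials may miss

    # Aim at the chosen intercept, or attempt toward the intended target on a
    # miss (the participant still reacts and reaches out).
    aim = intercept_point if intercept_point is not None else (target.anterior, target.vertical)
    ik = two_link_ik(anthro, aim)
    attempted_miss = intercept_point is None
    if ik is None:  # outside the annulus: clamp onto the reachable circle
        hipx, hipz = anthro.hip_pivot
        r = math.hypot(aim[0] - hipx, aim[1] - hipz)
        scale = anthro.reach_radius / r if r > 0 else 0.0
        aim = (hipx + (aim[0] - hipx) * scale, hipz + (aim[1] - hipz) * scale)
        ik = two_link_ik(anthro, aim)
        attempted_miss = True
    phi_total, psi_total = ik

    theta = float(plan_item.theta)
    lumbar_amp = participant.lumbar_share * phi_total + _anticipation(params, game, theta)
    hip_amp = phi_total - lumbar_amp  # lumped hip/lower-limb remainder

    if game == "reachality":
        t_end = start + movement_time + params.hold_s
    else:
        t_event = t_intercept if t_intercept is not None else start + movement_time
        t_end = max(t_event, start + movement_time) + params.post_s
    n = int(round(t_end * fs)) + 1
    t = np.arange(n) * dt

    s = minimum_jerk((t - start) / movement_time)
    lumbar_clean = lumbar_amp * s
    phi = lumbar_clean + hip_amp * s
    psi = psi_total * s
    hand_x, hand_z = _forward_hand(anthro, phi, psi)
    lumbar = lumbar_clean + rng.normal(0.0, participant.noise_sd, n)

    contact_time: Optional[float] = None
    if not attempted_miss:
        if traj is None:
            hit = (
                np.hypot(hand_x - aim[0], hand_z - aim[1])
                <= params.target_contact_radius
            )
            hit &= t > cue
        else:
            lead = params.cue_lead.get(game, 0.0)
            tb = t - (cue + lead)  # flight clock
            in_flight = (tb >= 0.0) & (tb <= traj.t[-1])
            bx = np.interp(tb, traj.t, traj.x)
            bz = np.interp(tb, traj.t, traj.z)
            hit = in_flight & (
                np.hypot(hand_x - bx, hand_z - bz) <= params.contact_radius
            )
        k = np.flatnonzero(hit)
        if k.size:
            contact_time = float(t[k[0]])

    return TrialRecording(
        t=t, lumbar_flexion=lumbar, hand_x=hand_x, hand_z=hand_z,
        cue_time=cue, contact_time=contact_time, game=game, theta=theta,
        hand=plan_item.hand, event_kind=plan_item.event_kind, fs=fs,
    )


def sample_participant(rng: np.random.Generator) -> ParticipantModel:
    """Draw one participant from the cohort trait distributions.

    Segment lengths are scaled to a young-adult cohort (mean stature ≈ 1.72 m);
    traits are mildly heterogeneous so between-subject variance is realistic.
    """
    anthro = Anthropometry(
        hip_height=max(0.7, rng.normal(0.93, 0.05)),
        trunk_length=max(0.35, rng.normal(0.47, 0.03)),
        arm_length=max(0.5, rng.normal(0.70, 0.04)),
    )
    return ParticipantModel(
        anthro=anthro,
        lumbar_share=float(np.clip(rng.normal(0.70, 0.08), 0.30, 0.95)),
        reaction_time=max(0.15, rng.normal(0.25, 0.03)),
        movement_time=max(0.6, rng.normal(1.1, 0.12)),
        noise_sd=0.3,
    )


def synthesize_cohort(
    n_participants: int,
    game_params: GameParams = GameParams(),
    seed: int = 0,
    participants: Optional[Sequence[ParticipantModel]] = None,
) -> list[TrialRecording]:
    """Realize a full session (fixed game order) for each of ``n`` participants.

    Each participant gets anthropometry-specific targets, per-target launch
    solutions, a seeded session plan, and one recording per plan item
    (40 reaches + 2×30 launches including ducks).  Two seeds give distinct
    cohorts with an identical design shape.
    """
    if n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    rng = np.random.default_rng(seed)
    recordings: list[TrialRecording] = []
    for i in range(n_participants):
        participant = (
            participants[i] if participants is not None else sample_participant(rng)
        )
        pid = f"P{i + 1:02d}"
        plan = plan_session(int(rng.integers(0, 2**31 - 1)), game_params.thetas)
        targets = {
            float(th): compute_target(participant.anthro, th)
            for th in game_params.thetas
        }
        trajs: dict[tuple[str, float], Trajectory] = {}
        for th, tp in targets.items():
            dsite = LaunchSite(*game_params.dodgeball_site)
            fsite = LaunchSite(*game_params.fish_site)
            dsol = solve_fixed_speed_angle(
                dsite, tp, game_params.dodgeball_speed, game_params.gravity
            )
            fsol = solve_fixed_apex(fsite, tp, game_params.fish_apex, game_params.gravity)
            trajs[("dodgeality", th)] = simulate_flight(
                dsite, dsol, game_params.gravity, 1.0 / game_params.fs
            )
            trajs[("fishality", th)] = simulate_flight(
                fsite, fsol, game_params.gravity, 1.0 / game_params.fs
            )
        for item in plan:
            if item.event_kind == "duck":
                payload = None
            elif item.game == "reachality":
                payload = targets[float(item.theta)]
            else:
                payload = (targets[float(item.theta)], trajs[(item.game, float(item.theta))])
            rec = synthesize_trial(
                item, participant, payload,
                seed=int(rng.integers(0, 2**31 - 1)), params=game_params,
            )
            rec.participant = pid
            recordings.append(rec)
    return recordings
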