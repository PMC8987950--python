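"""Session trial scheduling for the three-game graded protocol.

The session order is fixed: Reachality (static targets, self-paced) is played
first, then Fishality (high-arc fish), then Dodgeality (flat fast dodgeballs).

Reachality: the four heights are presented in fixed order from highest target
(θ=15°) to lowest (θ=60°); at each height the participant makes 5 right-hand
reaches followed by 5 left-hand reaches, with ~15 s rest between reaches and
~2 min between heights (40 reaches total).

Fishality / Dodgeality: 2 sets of 15 launches each, with an equal and
randomized distribution over five categories — the four target heights plus a
duck event (shark / black quacking ball) — i.e. exactly 3 launches per
category per set, order drawn as a seeded uniform permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .targets import DEFAULT_THETAS

__all__ = [
    "GAME_ORDER",
    "TrialPlanItem",
    "SessionPlan",
    "plan_reachality",
    "plan_launch_game",
    "plan_session",
]

Game = Literal["reachality", "fishality", "dodgeality"]
EventKind = Literal["reach", "launch", "duck"]
Hand = Literal["right", "left"]

#: Fixed gameplay order.
GAME_ORDER: tuple[Game, ...] = ("reachality", "fishality", "dodgeality")

REACHES_PER_HAND = 5
REST_BETWEEN_REACHES_S = 15.0
REST_BETWEEN_HEIGHTS_S = 120.0
SETS_PER_LAUNCH_GAME = 2
LAUNCHES_PER_SET = 15
DEFAULT_INTER_LAUNCH_REST_S = 5.0  # not reported for the deployed games


@dataclass(frozen=True)
class TrialPlanItem:
    """One scheduled trial.

    Duck items carry no θ; only Reachality items carry a hand.
    """

    game: Game
    event_kind: EventKind
    theta: Optional[float]
    hand: Optional[Hand]
    set_index: int
    trial_index: int
    rest_after: float

    def __post_init__(self) -> None:
        if self.event_kind == "duck" and self.theta is not None:
            raise ValueError("duck items carry no theta")
        if self.game == "reachality" and self.hand is None:
            raise ValueError("reachality items carry a hand")
        if self.game != "reachality" and self.hand is not None:
            raise ValueError("launch-game items carry no hand")


@dataclass(frozen=True)
class SessionPlan:
    """Ordered trial list with the seed that generated any randomized parts."""

    items: tuple[TrialPlanItem, ...]
    rng_seed: Optional[int]

    def __iter__(self):
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for item in self.items:
            key = "duck" if item.event_kind == "duck" else f"theta{item.theta:g}"
            counts[key] = counts.get(key, 0) + 1
        return counts


def plan_reachality(
    thetas: Sequence[float] = DEFAULT_THETAS,
    reaches_per_hand: int = REACHES_PER_HAND,
) -> SessionPlan:
    """Fixed-order reaching block: highest→lowest target, right then left hand.

    θ=15° is the highest target, so ascending θ runs highest→lowest.
    """
    items: list[TrialPlanItem] = []
    trial = 0
    n_heights = len(thetas)
    for h_idx, theta in enumerate(thetas):
        for hand in ("right", "left"):
            for rep in range(reaches_per_hand):
                last_of_height = hand == "left" and rep == reaches_per_hand - 1
                last_of_block = last_of_height and h_idx == n_heights - 1
                rest = (
                    0.0 if last_of_block
                    else REST_BETWEEN_HEIGHTS_S if last_of_height
                    else REST_BETWEEN_REACHES_S
                )
                items.append(
                    TrialPlanItem(
                        game="reachality", event_kind="reach", theta=float(theta),
                        hand=hand, set_index=0, trial_index=trial, rest_after=rest,
                    )
                )
                trial += 1
    return SessionPlan(items=tuple(items), rng_seed=None)


def plan_launch_game(
    game: Game,
    seed: int,
    thetas: Sequence[float] = DEFAULT_THETAS,
    inter_launch_rest: float = DEFAULT_INTER_LAUNCH_REST_S,
) -> SessionPlan:
    """Two sets of 15 launches, balanced over 4 heights + duck, seeded shuffle.

    Each set holds exactly ``LAUNCHES_PER_SET / 5 = 3`` launches of each
    category; the within-set order is a uniform permutation from
    ``numpy.random.default_rng(seed)``, so identical seeds give identical
    plans.
    """
    if game not in ("fishality", "dodgeality"):
        raise ValueError(f"launch games are fishality/dodgeality, got {game!r}")
    if len(thetas) != 4:
        raise ValueError("the launch protocol balances over exactly 4 heights + duck")
    per_cat, rem = divmod(LAUNCHES_PER_SET, len(thetas) + 1)
    assert rem == 0
    rng = np.random.default_rng(seed)
    categories: list[Optional[float]] = [float(t) for t in thetas] + [None]
    items: list[TrialPlanItem] = []
    trial = 0
    for set_idx in range(SETS_PER_LAUNCH_GAME):
        deck = [c for c in categories for _ in range(per_cat)]
        order = rng.permutation(len(deck))
        for j in order:
            theta = deck[j]
            items.append(
                TrialPlanItem(
                    game=game,
                    event_kind="duck" if theta is None else "launch",
                    theta=theta,
                    hand=None,
                    set_index=set_idx,
                    trial_index=trial,
                    rest_after=inter_launch_rest,
                )
            )
            trial += 1
    return SessionPlan(items=tuple(items), rng_seed=int(seed))


def plan_session(seed: int, thetas: Sequence[float] = DEFAULT_THETAS) -> SessionPlan:
    """Full session in the fixed game order, launch games seeded from ``seed``."""
    rng = np.random.default_rng(seed)
    fish_seed, dodge_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    items = (
        plan_reachality(thetas).items
        + plan_launch_game("fishality", fish_seed, thetas).items
        + plan_launch_game("dodgeality", dodge_seed, thetas).items
    )
    return SessionPlan(items=items, rng_seed=int(seed))
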