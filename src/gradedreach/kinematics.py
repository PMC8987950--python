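"""Trial reduction: smoothing/differentiation, windowing, outcomes, screening.

Joint-angle series are smoothed and differentiated with a 41-point,
fourth-order Savitzky–Golay filter (local least-squares polynomial fits,
mirror-padded at the boundaries, derivative scaled by the sampling rate).
Outcomes per trial:

* lumbar flexion excursion — peak smoothed lumbar angle within the analysis
  window minus its value at window onset (degrees);
* peak lumbar flexion velocity — maximum of the smoothed derivative within
  the window (degrees/s);
* impact location — hand position at target contact, anterior and vertical,
  relative to the midpoint of the feet (m).

The analysis window runs from the movement cue to 200 ms after target
contact; missed-but-attempted trials instead end at the peak forward hand
displacement.  Trials with an apparent lack of lumbar motion (excursion below
a configurable 2° threshold) are excluded; misses with a genuine reaching
attempt are retained.  Only right-hand reaching is analyzed, and outcomes are
averaged per participant × game × height into the cohort table the
repeated-measures statistics consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthesis import TrialRecording

__all__ = [
    "FilterSpec",
    "TrialMetrics",
    "CohortTable",
    "sg_smooth_diff",
    "analysis_window",
    "compute_metrics",
    "screen_trial",
    "aggregate",
]

OUTCOME_COLUMNS = (
    "lumbar_excursion_deg",
    "peak_lumbar_velocity_deg_s",
    "impact_ap_m",
    "impact_vertical_m",
)


@dataclass(frozen=True)
class FilterSpec:
    """Savitzky–Golay filter parameters."""

    window: int = 41  # samples, odd
    polyorder: int = 4
    rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError(f"window must be odd and ≥3, got {self.window}")
        if not 0 <= self.polyorder < self.window:
            raise ValueError("polyorder must satisfy 0 ≤ polyorder < window")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class TrialMetrics:
    """Per-trial outcomes plus inclusion status and provenance labels."""

    lumbar_excursion_deg: float
    peak_lumbar_velocity_deg_s: float
    impact_ap_m: float  # NaN for misses
    impact_vertical_m: float  # NaN for misses
    included: bool = True
    exclusion_reason: Optional[str] = None
    participant: str = ""
    game: str = ""
    theta: Optional[float] = None
    hand: Optional[str] = None
    event_kind: str = "reach"
    missed: bool = False


@dataclass
class CohortTable:
    """Participant × game × height cell means, long format.

    ``data`` has one row per (participant, game, theta) with the mean of each
    outcome over that participant's included trials; ``incomplete`` lists
    (participant, game, theta) cells with no included trial — the
    repeated-measures ANOVA needs every cell of the 3 × 4 within-subject
    design.
    """

    data: pd.DataFrame
    incomplete: list[tuple[str, str, float]]

    @property
    def complete(self) -> bool:
        return not self.incomplete


def sg_smooth_diff(
    series: np.ndarray, spec: FilterSpec = FilterSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth a series and compute its first derivative (units/s).

    Mirror padding at the boundaries; derivative scaled by the sampling
    interval.  Raises ``ValueError`` when the series is shorter than the
    filter window.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if series.size < spec.window:
        raise ValueError(
            f"series length {series.size} is shorter than the filter window {spec.window}"
        )
    smoothed = savgol_filter(series, spec.window, spec.polyorder, mode="mirror")
    deriv = savgol_filter(
        series, spec.window, spec.polyorder, deriv=1, delta=1.0 / spec.rate,
        mode="mirror",
    )
    return smoothed, deriv


def analysis_window(rec: TrialRecording) -> tuple[float, float]:
    """Analysis interval: cue to 200 ms after contact (clipped to the record).

    For missed-but-attempted trials the window ends at the peak forward hand
    displacement after the cue.
    """
    if rec.cue_time is None or not math.isfinite(rec.cue_time):
        raise ValueError("trial has no movement cue")
    t_start = rec.cue_time
    t_last = float(rec.t[-1])
    if rec.contact_time is not None:
        t_end = min(rec.contact_time + 0.200, t_last)
    else:
        after = rec.t >= t_start
        if not np.any(after):
            raise ValueError("no samples after the cue")
        i = int(np.argmax(rec.hand_x[after]))
        t_end = float(rec.t[after][i])
    return t_start, t_end


def compute_metrics(
    rec: TrialRecording,
    spec: FilterSpec = FilterSpec(),
    excursion_mode: Literal["peak_minus_onset", "net"] = "peak_minus_onset",
) -> TrialMetrics:
    """Extract the trial outcomes through the Savitzky–Golay pipeline.

    ``peak_minus_onset`` (default) takes the window maximum of the smoothed
    lumbar angle minus its onset value; ``net`` takes the end-minus-onset
    change instead.
    """
    t_start, t_end = analysis_window(rec)
    smoothed, deriv = sg_smooth_diff(rec.lumbar_flexion, spec)
    win = (rec.t >= t_start - 1e-9) & (rec.t <= t_end + 1e-9)
    if not np.any(win):
        raise ValueError("empty analysis window")
    onset = smoothed[win][0]
    if excursion_mode == "peak_minus_onset":
        excursion = float(np.max(smoothed[win]) - onset)
    elif excursion_mode == "net":
        excursion = float(smoothed[win][-1] - onset)
    else:
        raise ValueError(f"unknown excursion_mode {excursion_mode!r}")
    peak_vel = float(np.max(deriv[win]))

    if rec.contact_time is not None:
        i = int(np.argmin(np.abs(rec.t - rec.contact_time)))
        impact_ap, impact_z = float(rec.hand_x[i]), float(rec.hand_z[i])
        missed = False
    else:
        impact_ap = impact_z = float("nan")
        missed = True

    return TrialMetrics(
        lumbar_excursion_deg=excursion,
        peak_lumbar_velocity_deg_s=peak_vel,
        impact_ap_m=impact_ap,
        impact_vertical_m=impact_z,
        participant=rec.participant,
        game=rec.game,
        theta=rec.theta,
        hand=rec.hand,
        event_kind=rec.event_kind,
        missed=missed,
    )


def screen_trial(metrics: TrialMetrics, min_excursion: float = 2.0) -> TrialMetrics:
    """Apply the lack-of-lumbar-motion exclusion rule.

    A trial is excluded iff its excursion falls below ``min_excursion``
    degrees (the automated surrogate for the study's visual review); missed
    trials with a genuine attempt are retained.
    """
    excluded = metrics.lumbar_excursion_deg < min_excursion
    return replace(
        metrics,
        included=not excluded,
        exclusion_reason="no_lumbar_motion" if excluded else None,
    )


def aggregate(
    trials: Iterable[TrialMetrics],
    thetas: Optional[Sequence[float]] = None,
) -> CohortTable:
    """Average included trials into the participant × game × height table.

    Left-hand Reachality reaches and duck events are dropped before
    averaging (only right-hand reaching is analyzed); impact-location means
    ignore missed trials (no contact, so no impact sample).
    """
    rows = []
    for m in trials:
        if m.event_kind == "duck" or m.theta is None:
            continue
        if m.game == "reachality" and m.hand != "right":
            continue
        if not m.included:
            continue
        rows.append(
            {
                "participant": m.participant,
                "game": m.game,
                "theta": float(m.theta),
                "lumbar_excursion_deg": m.lumbar_excursion_deg,
                "peak_lumbar_velocity_deg_s": m.peak_lumbar_velocity_deg_s,
                "impact_ap_m": m.impact_ap_m,
                "impact_vertical_m": m.impact_vertical_m,
            }
        )
    if not rows:
        return CohortTable(
            data=pd.DataFrame(
                columns=["participant", "game", "theta", *OUTCOME_COLUMNS]
            ),
            incomplete=[],
        )
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["participant", "game", "theta"], as_index=False)
        .agg({c: "mean" for c in OUTCOME_COLUMNS})  # NaN-skipping cell means
        .sort_values(["participant", "game", "theta"], ignore_index=True)
    )
    participants = sorted(table["participant"].unique())
    games = sorted(table["game"].unique())
    theta_levels = sorted(thetas) if thetas is not None else sorted(table["theta"].unique())
    have = set(zip(table["participant"], table["game"], table["theta"]))
    incomplete = [
        (p, g, th)
        for p in participants
        for g in games
        for th in theta_levels
        if (p, g, th) not in have
    ]
    return CohortTable(data=table, incomplete=incomplete)
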