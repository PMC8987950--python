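"""File formats and suite configuration.

Trial recordings travel as TSV (``t_s, lumbar_deg, hand_x_m, hand_z_m``) with
a JSON sidecar (``<name>.json``) for event markers and labels; cohort tables
as CSV.  Both round-trip losslessly (floats serialized at full precision).
Suite configuration loads from YAML or JSON and is validated against the
module preconditions before any stage runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .kinematics import OUTCOME_COLUMNS, CohortTable, FilterSpec
from .synthesis import GameParams, TrialRecording
from .targets import DEFAULT_THETAS

__all__ = [
    "TrialParseError",
    "SuiteConfig",
    "write_trial_tsv",
    "read_trial_tsv",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_config",
]

TRIAL_COLUMNS = ("t_s", "lumbar_deg", "hand_x_m", "hand_z_m")
COHORT_KEY_COLUMNS = ("participant", "game", "theta")


class TrialParseError(ValueError):
    """Malformed trial TSV/CSV, with a line number where known."""


def _sidecar(path: Union[str, Path]) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def write_trial_tsv(rec: TrialRecording, path: Union[str, Path]) -> Path:
    """Write a recording as TSV plus a JSON sidecar for events and labels."""
    path = Path(path)
    cols = np.column_stack([rec.t, rec.lumbar_flexion, rec.hand_x, rec.hand_z])
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(TRIAL_COLUMNS) + "\n")
        for row in cols:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    meta = {
        "cue_time": rec.cue_time,
        "contact_time": rec.contact_time,
        "game": rec.game,
        "theta": rec.theta,
        "hand": rec.hand,
        "event_kind": rec.event_kind,
        "participant": rec.participant,
        "fs": rec.fs,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1) + "\n")
    return path


def read_trial_tsv(path: Union[str, Path]) -> TrialRecording:
    """Read a recording written by :func:`write_trial_tsv` (CRLF tolerated)."""
    path = Path(path)
    with open(path, "r", newline=None) as fh:  # universal newlines
        header = fh.readline().strip().split("\t")
        if tuple(header) != TRIAL_COLUMNS:
            raise TrialParseError(
                f"{path}:1: expected header {list(TRIAL_COLUMNS)}, got {header}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(TRIAL_COLUMNS):
                raise TrialParseError(
                    f"{path}:{lineno}: expected {len(TRIAL_COLUMNS)} fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise TrialParseError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise TrialParseError(f"{path}: no data rows")
    data = np.asarray(rows)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise TrialParseError(f"{sidecar}: missing events/labels sidecar")
    meta = json.loads(sidecar.read_text())
    return TrialRecording(
        t=data[:, 0], lumbar_flexion=data[:, 1], hand_x=data[:, 2], hand_z=data[:, 3],
        cue_time=meta["cue_time"], contact_time=meta["contact_time"],
        game=meta["game"], theta=meta["theta"], hand=meta["hand"],
        event_kind=meta.get("event_kind", "reach"),
        participant=meta.get("participant", ""), fs=meta.get("fs", 100.0),
    )


def write_cohort_csv(table: CohortTable, path: Union[str, Path]) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")
    return path


def read_cohort_csv(path: Union[str, Path]) -> CohortTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise TrialParseError(f"{path}: {exc}") from exc
    missing = [c for c in (*COHORT_KEY_COLUMNS, *OUTCOME_COLUMNS) if c not in df.columns]
    if missing:
        raise TrialParseError(f"{path}: missing columns {missing}")
    participants = sorted(df["participant"].unique())
    games = sorted(df["game"].unique())
    thetas = sorted(df["theta"].unique())
    have = set(zip(df["participant"], df["game"], df["theta"]))
    incomplete = [
        (p, g, th)
        for p in participants
        for g in games
        for th in thetas
        if (p, g, th) not in have
    ]
    return CohortTable(data=df, incomplete=incomplete)


@dataclass
class SuiteConfig:
    """Everything a seeded end-to-end run needs.

    Defaults reproduce the deployed protocol: 15/30/45/60° targets, an 8 m/s
    flat dodgeball from (3.0, 1.6) m, a 2.0 m-apex fish from (2.5, 0) m,
    100 Hz sampling, the 41-point/4th-order filter, a 2° exclusion threshold
    and α = .05.
    """

    thetas: tuple[float, ...] = DEFAULT_THETAS
    gravity: float = 9.81
    dodgeball_speed: float = 8.0
    dodgeball_site: tuple[float, float] = (3.0, 1.6)
    fish_apex: float = 2.0
    fish_site: tuple[float, float] = (2.5, 0.0)
    fs: float = 100.0
    filter_window: int = 41
    filter_order: int = 4
    min_excursion_deg: float = 2.0
    alpha: float = 0.05
    anticipation_deg: float = 12.0
    n_participants: int = 31
    seed: int = 0

    def __post_init__(self) -> None:
        thetas = tuple(float(t) for t in self.thetas)
        if any(not 0.0 <= t < 90.0 for t in thetas):
            raise ValueError("thetas must lie in [0, 90) degrees")
        if any(b <= a for a, b in zip(thetas, thetas[1:])):
            raise ValueError("thetas must be strictly increasing")
        self.thetas = thetas
        self.dodgeball_site = tuple(float(v) for v in self.dodgeball_site)
        self.fish_site = tuple(float(v) for v in self.fish_site)
        if self.gravity <= 0 or self.dodgeball_speed <= 0 or self.fs <= 0:
            raise ValueError("gravity, launch speed and sampling rate must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_excursion_deg < 0:
            raise ValueError("min_excursion_deg must be non-negative")
        FilterSpec(self.filter_window, self.filter_order, self.fs)  # validates

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.filter_window, self.filter_order, self.fs)

    @property
    def game_params(self) -> GameParams:
        return GameParams(
            thetas=self.thetas,
            gravity=self.gravity,
            dodgeball_speed=self.dodgeball_speed,
            dodgeball_site=self.dodgeball_site,
            fish_apex=self.fish_apex,
            fish_site=self.fish_site,
            fs=self.fs,
            anticipation_deg=self.anticipation_deg,
        )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SuiteConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["thetas"] = list(self.thetas)
        d["dodgeball_site"] = list(self.dodgeball_site)
        d["fish_site"] = list(self.fish_site)
        return d


def load_config(path: Union[str, Path, None]) -> SuiteConfig:
    """Load a YAML or JSON config; ``None`` yields the defaults."""
    if path is None:
        return SuiteConfig()
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        return SuiteConfig()
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a mapping")
    return SuiteConfig.from_dict(data)
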