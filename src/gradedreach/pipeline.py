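"""Seeded end-to-end runs: targets → launches → plans → cohort → metrics → stats.

Every stage error is re-raised with the stage name attached, and all written
artifacts are listed in a SHA-256 manifest so identical seeds can be checked
to reproduce a bundle bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .gameio import SuiteConfig, write_cohort_csv, write_trial_tsv
from .kinematics import CohortTable, aggregate, compute_metrics, screen_trial
from .rmstats import RMAnovaResults, RepeatedMeasuresAnova
from .synthesis import synthesize_cohort

__all__ = ["StageError", "RunBundle", "run_end_to_end"]

log = logging.getLogger("gradedreach")

OUTCOMES = (
    "lumbar_excursion_deg",
    "peak_lumbar_velocity_deg_s",
    "impact_ap_m",
    "impact_vertical_m",
)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names where."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunBundle:
    """Everything a run produced, in memory plus on disk."""

    config: SuiteConfig
    metrics: pd.DataFrame
    cohort: CohortTable
    anova: dict[str, RMAnovaResults]
    outdir: Optional[Path]
    manifest: dict[str, str]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_end_to_end(
    config: SuiteConfig,
    n_participants: Optional[int] = None,
    seed: Optional[int] = None,
    outdir: Optional[Path] = None,
    write_trials: bool = False,
) -> RunBundle:
    """Run the full suite once with a single seed.

    Writes per-trial metrics, the cohort table, the statistics report and a
    manifest to ``outdir`` when given; ``write_trials`` additionally dumps
    every trial TSV (large).  The same config and seed reproduce every
    artifact byte-for-byte on one platform.
    """
    n = n_participants if n_participants is not None else config.n_participants
    seed = seed if seed is not None else config.seed
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    t0 = time.perf_counter()
    try:
        recordings = synthesize_cohort(n, config.game_params, seed)
    except Exception as exc:
        raise StageError("synthesis (targets/ballistics/protocol/motion)", exc) from exc
    log.info("synthesized %d recordings in %.1fs", len(recordings), time.perf_counter() - t0)

    if outdir is not None and write_trials:
        trials_dir = outdir / "trials"
        trials_dir.mkdir(exist_ok=True)
        for i, rec in enumerate(recordings):
            p = write_trial_tsv(rec, trials_dir / f"trial_{i:05d}.tsv")
            manifest[str(p.relative_to(outdir))] = _sha256(p)

    t0 = time.perf_counter()
    try:
        spec = config.filter_spec
        metrics = [
            screen_trial(compute_metrics(r, spec), config.min_excursion_deg)
            for r in recordings
            if r.event_kind != "duck"
        ]
    except Exception as exc:
        raise StageError("kinematic analysis", exc) from exc
    log.info("reduced %d trials in %.1fs", len(metrics), time.perf_counter() - t0)

    metrics_df = pd.DataFrame(
        [
            {
                "participant": m.participant,
                "game": m.game,
                "theta": m.theta,
                "hand": m.hand,
                "event_kind": m.event_kind,
                **{c: getattr(m, c) for c in OUTCOMES},
                "included": m.included,
                "exclusion_reason": m.exclusion_reason,
                "missed": m.missed,
            }
            for m in metrics
        ]
    )

    try:
        cohort = aggregate(metrics, thetas=config.thetas)
    except Exception as exc:
        raise StageError("aggregation", exc) from exc
    if cohort.incomplete:
        log.warning("incomplete cells: %s", cohort.incomplete)

    t0 = time.perf_counter()
    anova: dict[str, RMAnovaResults] = {}
    try:
        for outcome in OUTCOMES:
            model = RepeatedMeasuresAnova.from_cohort(cohort, outcome)
            anova[outcome] = model.fit()
    except Exception as exc:
        raise StageError("repeated-measures statistics", exc) from exc
    log.info("fitted %d ANOVAs in %.1fs", len(anova), time.perf_counter() - t0)

    if outdir is not None:
        p = outdir / "trial_metrics.csv"
        metrics_df.to_csv(p, index=False, lineterminator="\n", float_format="%.17g")
        manifest[p.name] = _sha256(p)
        p = write_cohort_csv(cohort, outdir / "cohort_table.csv")
        manifest[p.name] = _sha256(p)

        report = {
            outcome: [
                {
                    "effect": e.effect,
                    "F": e.F,
                    "df1": e.df1,
                    "df2": e.df2,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "epsilon_gg": e.epsilon_gg,
                    "mauchly_p": e.mauchly_p,
                    "gg_corrected": e.corrected,
                }
                for e in res.effects
            ]
            for outcome, res in anova.items()
        }
        p = outdir / "anova_report.json"
        p.write_text(json.dumps(report, indent=1) + "\n")
        manifest[p.name] = _sha256(p)
        p = outdir / "anova_summary.txt"
        p.write_text("\n\n".join(res.summary() for res in anova.values()) + "\n")
        manifest[p.name] = _sha256(p)
        p = outdir / "config.json"
        p.write_text(json.dumps({**config.to_dict(), "run_seed": seed, "run_n": n},
                                indent=1, sort_keys=True) + "\n")
        manifest[p.name] = _sha256(p)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )

    return RunBundle(
        config=config, metrics=metrics_df, cohort=cohort, anova=anova,
        outdir=outdir, manifest=manifest,
    )
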