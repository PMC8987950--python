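"""Repeated-measures statistical battery for the game-comparison design.

The study design is fully within-subject: every participant plays all three
games at all four target heights, and each outcome is a participant × game ×
height cell mean.  The battery is

* Shapiro–Wilk normality screening;
* a two-way repeated-measures ANOVA (game × height), each effect tested
  against its subject-by-effect interaction error term;
* Mauchly's sphericity test per effect, with Greenhouse–Geisser ε applied to
  both degrees of freedom when sphericity is rejected (p < .05);
* partial η² = SS_effect / (SS_effect + SS_error) with the conventional
  thresholds (>0.25 moderate, >0.64 strong);
* LSD (uncorrected pairwise paired-t) post hocs and per-height simple
  effects (one-way RM-ANOVA of game at each height).

The modelling surface follows the statsmodels idiom: build a
:class:`RepeatedMeasuresAnova` from a long-format DataFrame, call ``fit()``,
and read estimates, diagnostics and ``summary()`` off the returned
:class:`RMAnovaResults`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .kinematics import CohortTable

__all__ = [
    "AnovaResult",
    "PosthocResult",
    "RepeatedMeasuresAnova",
    "RMAnovaResults",
    "shapiro_wilk",
    "rm_anova_2way",
    "eta_sq_from_f",
    "lsd_posthoc",
    "simple_effects",
    "classify_effect_size",
    "simulate_null_type1",
]

Correction = Literal["auto", "always", "never"]


@dataclass(frozen=True)
class AnovaResult:
    """One tested effect: F, (possibly ε-corrected) dfs, p, effect size."""

    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    epsilon_gg: Optional[float] = None
    mauchly_p: Optional[float] = None
    corrected: bool = False

    def __str__(self) -> str:
        return (
            f"{self.effect}: F({self.df1:g},{self.df2:g})={self.F:.3f}, "
            f"p={self.p:.4g}, eta_p^2={self.partial_eta_sq:.3f}"
            + (" (GG-corrected)" if self.corrected else "")
        )


@dataclass(frozen=True)
class PosthocResult:
    """One LSD pair: uncorrected paired-t comparison of two condition levels."""

    level_a: str
    level_b: str
    mean_diff: float
    t: float
    df: int
    p: float


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston's algorithm), for 3 ≤ n ≤ 5000."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk needs 3 ≤ n ≤ 5000, got n={x.size}")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def eta_sq_from_f(F: float, df1: float, df2: float) -> float:
    """Partial η² from an F statistic: ``F·df1 / (F·df1 + df2)``.

    Algebraically identical to SS_effect / (SS_effect + SS_error).
    """
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return F * df1 / (F * df1 + df2)


def classify_effect_size(partial_eta_sq: float) -> str:
    """Conventional bands: >0.64 strong, >0.25 moderate, otherwise small."""
    if not 0.0 <= partial_eta_sq <= 1.0:
        raise ValueError(f"partial eta squared must be in [0, 1], got {partial_eta_sq}")
    if partial_eta_sq > 0.64:
        return "strong"
    if partial_eta_sq > 0.25:
        return "moderate"
    return "small"


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1) × k orthonormal contrast matrix (Helmert, normalized)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def _sphericity(D: np.ndarray) -> tuple[Optional[float], float]:
    """Mauchly p and GG ε from subject scores on orthonormal contrasts.

    ``D`` is n × p (p = effect df).  ε̂ = tr(S)² / (p · tr(S²)).  The Mauchly
    chi-square approximation needs n − 1 > p and p > 1; otherwise the test is
    undefined and ``None`` is returned (ε is still computed, and is exactly 1
    when p = 1).
    """
    n, p = D.shape
    if p == 1:
        return None, 1.0
    S = np.cov(D, rowvar=False, ddof=1)
    tr = float(np.trace(S))
    tr2 = float(np.trace(S @ S))
    eps = tr * tr / (p * tr2) if tr2 > 0 else 1.0
    eps = min(1.0, max(1.0 / p, eps))
    if n - 1 <= p:
        return None, eps
    det = float(np.linalg.det(S))
    if det <= 0 or tr <= 0:
        return None, eps
    W = det / (tr / p) ** p
    # Box's chi-square approximation with the second-order term (as in
    # SPSS / ezANOVA): p ≈ P(χ²_df > c) + w2·(P(χ²_df+4 > c) − P(χ²_df > c))
    f = 1.0 - (2.0 * p * p + p + 2.0) / (6.0 * p * (n - 1.0))
    k = p + 1  # factor levels
    w2 = (
        (p + 2.0) * (p - 1.0) * (p - 2.0) * (2.0 * p**3 + 6.0 * p**2 + 3.0 * k + 2.0)
        / (288.0 * ((n - 1.0) * p * f) ** 2)
    )
    chi2 = -(n - 1.0) * f * math.log(W)
    df = p * (p + 1.0) / 2.0 - 1.0
    p1 = float(sps.chi2.sf(chi2, df))
    p2 = float(sps.chi2.sf(chi2, df + 4.0))
    return p1 + w2 * (p2 - p1), eps


def _f_test(
    ss_eff: float,
    ss_err: float,
    df1: int,
    df2: int,
    effect: str,
    D: np.ndarray,
    correction: Correction,
    ss_scale: float = 0.0,
) -> AnovaResult:
    mauchly_p, eps = _sphericity(D)
    # degenerate effects: SS indistinguishable from rounding noise at the
    # data's scale count as exactly zero (flat tables give F = 0, p = 1)
    tol = 1e-12 * max(ss_scale, 1e-30)
    if ss_eff <= tol:
        ss_eff = 0.0
    if ss_err <= tol:
        ss_err = 0.0
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    F = 0.0 if ms_eff == 0.0 else (math.inf if ms_err == 0.0 else ms_eff / ms_err)
    eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    apply_gg = correction == "always" or (
        correction == "auto" and mauchly_p is not None and mauchly_p < 0.05
    )
    rdf1, rdf2 = (df1 * eps, df2 * eps) if apply_gg else (float(df1), float(df2))
    if F == 0.0:
        p = 1.0
    elif math.isinf(F):
        p = 0.0
    else:
        p = float(sps.f.sf(F, rdf1, rdf2))
    return AnovaResult(
        effect=effect, F=F, df1=rdf1, df2=rdf2, p=p, partial_eta_sq=eta,
        epsilon_gg=eps, mauchly_p=mauchly_p, corrected=apply_gg,
    )


def _fit_oneway(Y: np.ndarray, effect: str, correction: Correction) -> AnovaResult:
    """One-way within-subject ANOVA on an n × k cell-mean array."""
    n, k = Y.shape
    grand = Y.mean()
    m_s = Y.mean(axis=1, keepdims=True)
    m_c = Y.mean(axis=0, keepdims=True)
    ss_eff = float(n * ((m_c - grand) ** 2).sum())
    resid = Y - m_s - m_c + grand
    ss_err = float((resid**2).sum())
    D = Y @ _orthonormal_contrasts(k).T
    ss_scale = float(((Y - grand) ** 2).sum())
    return _f_test(
        ss_eff, ss_err, k - 1, (k - 1) * (n - 1), effect, D, correction, ss_scale
    )


def _fit_twoway(
    Y: np.ndarray, names: tuple[str, str], correction: Correction
) -> list[AnovaResult]:
    """Two-way within-subject ANOVA on an n × a × b cell array."""
    n, a, b = Y.shape
    grand = Y.mean()
    m_i = Y.mean(axis=(1, 2))  # subject
    m_j = Y.mean(axis=(0, 2))  # factor A
    m_k = Y.mean(axis=(0, 1))  # factor B
    m_ij = Y.mean(axis=2)
    m_ik = Y.mean(axis=1)
    m_jk = Y.mean(axis=0)

    ss_a = float(n * b * ((m_j - grand) ** 2).sum())
    ss_b = float(n * a * ((m_k - grand) ** 2).sum())
    ss_ab = float(
        n * ((m_jk - m_j[:, None] - m_k[None, :] + grand) ** 2).sum()
    )
    ss_as = float(b * ((m_ij - m_i[:, None] - m_j[None, :] + grand) ** 2).sum())
    ss_bs = float(a * ((m_ik - m_i[:, None] - m_k[None, :] + grand) ** 2).sum())
    ss_total = float(((Y - grand) ** 2).sum())
    ss_subj = float(a * b * ((m_i - grand) ** 2).sum())
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    D_a = m_ij @ ca.T
    D_b = m_ik @ cb.T
    D_ab = Y.reshape(n, a * b) @ np.kron(ca, cb).T

    name_a, name_b = names
    return [
        _f_test(
            ss_a, ss_as, a - 1, (a - 1) * (n - 1), name_a, D_a, correction, ss_total
        ),
        _f_test(
            ss_b, ss_bs, b - 1, (b - 1) * (n - 1), name_b, D_b, correction, ss_total
        ),
        _f_test(
            ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1),
            f"{name_a}*{name_b}", D_ab, correction, ss_total,
        ),
    ]


class RepeatedMeasuresAnova:
    """Within-subject ANOVA model for one outcome of the cohort table.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format: one row per subject × condition cell.
    dv : str
        Outcome column.
    within : str or (str, str)
        One or two within-subject factor columns (e.g. ``("game", "theta")``).
    subject : str
        Subject identifier column.

    The design must be complete and balanced (one observation per subject per
    cell); incomplete designs raise at construction.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str,
        within: Union[str, Sequence[str]],
        subject: str = "participant",
    ) -> None:
        self.dv = dv
        self.within = (within,) if isinstance(within, str) else tuple(within)
        if len(self.within) not in (1, 2):
            raise ValueError("within must name one or two factors")
        self.subject = subject
        cols = [subject, *self.within, dv]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = data[cols].dropna()
        self.subjects = sorted(df[subject].unique())
        self.levels = tuple(sorted(df[f].unique()) for f in self.within)
        if len(self.subjects) < 2:
            raise ValueError("need at least 2 subjects")
        shape = (len(self.subjects), *(len(lv) for lv in self.levels))
        pivot = df.pivot_table(
            index=subject, columns=list(self.within), values=dv, aggfunc="mean"
        )
        full = pd.MultiIndex.from_product(self.levels) if len(self.within) == 2 else pd.Index(
            self.levels[0]
        )
        pivot = pivot.reindex(index=self.subjects, columns=full)
        if pivot.isna().any().any():
            raise ValueError(
                "incomplete within-subject design: every subject needs every cell"
            )
        self.Y = pivot.to_numpy(dtype=float).reshape(shape)
        self.data = df

    @classmethod
    def from_cohort(
        cls, table: CohortTable, outcome: str, within: Sequence[str] = ("game", "theta")
    ) -> "RepeatedMeasuresAnova":
        if not table.complete:
            raise ValueError(
                f"cohort table has {len(table.incomplete)} empty cells: "
                f"{table.incomplete[:5]}…"
            )
        return cls(table.data, dv=outcome, within=within)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        dv: str,
        within: Union[str, Sequence[str]],
        subject: str = "participant",
    ) -> "RepeatedMeasuresAnova":
        """Constructor alias in the statsmodels ``from_formula`` spirit."""
        return cls(data, dv=dv, within=within, subject=subject)

    def fit(self, correction: Correction = "auto") -> "RMAnovaResults":
        """Run the decomposition; GG correction per ``correction`` policy."""
        if len(self.within) == 1:
            effects = [_fit_oneway(self.Y, self.within[0], correction)]
        else:
            effects = _fit_twoway(self.Y, (self.within[0], self.within[1]), correction)
        return RMAnovaResults(self, effects)


class RMAnovaResults:
    """Fitted effects with diagnostics, post hocs and a printable summary."""

    def __init__(self, model: RepeatedMeasuresAnova, effects: list[AnovaResult]) -> None:
        self.model = model
        self.effects = effects

    def __iter__(self):
        return iter(self.effects)

    def effect(self, name: str) -> AnovaResult:
        for e in self.effects:
            if e.effect == name:
                return e
        raise KeyError(name)

    @property
    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "F": e.F,
                    "df1": e.df1,
                    "df2": e.df2,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "effect_size": classify_effect_size(min(1.0, e.partial_eta_sq)),
                    "epsilon_gg": e.epsilon_gg,
                    "mauchly_p": e.mauchly_p,
                    "gg_corrected": e.corrected,
                }
                for e in self.effects
            ]
        )

    def summary(self) -> str:
        """Human-readable table: effect, F(df1,df2), p, η²p, sphericity."""
        lines = [
            f"Repeated-measures ANOVA: {self.model.dv}",
            f"  subjects: {len(self.model.subjects)}, "
            f"within: {' × '.join(self.model.within)}",
            f"{'effect':<16}{'F(df1,df2)':<26}{'p':<12}{'eta_p^2':<10}"
            f"{'size':<10}{'GG':<4}",
        ]
        for e in self.effects:
            fstr = f"F({e.df1:.1f},{e.df2:.1f})={e.F:.3f}"
            pstr = "<.001" if e.p < 0.001 else f"{e.p:.3f}"
            lines.append(
                f"{e.effect:<16}{fstr:<26}{pstr:<12}{e.partial_eta_sq:<10.3f}"
                f"{classify_effect_size(min(1.0, e.partial_eta_sq)):<10}"
                f"{'yes' if e.corrected else 'no':<4}"
            )
        return "\n".join(lines)

    def posthoc(self, factor: Optional[str] = None) -> list[PosthocResult]:
        """LSD pairwise paired t-tests on one factor's marginal means."""
        factor = factor or self.model.within[0]
        axis = self.model.within.index(factor)
        Y = self.model.Y
        if Y.ndim == 3:
            M = Y.mean(axis=2) if axis == 0 else Y.mean(axis=1)
        else:
            M = Y
        levels = self.model.levels[axis]
        out = []
        for i, j in itertools.combinations(range(len(levels)), 2):
            diff = M[:, i] - M[:, j]
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(M[:, i], M[:, j])
            out.append(
                PosthocResult(
                    level_a=str(levels[i]), level_b=str(levels[j]),
                    mean_diff=float(diff.mean()), t=float(t),
                    df=M.shape[0] - 1, p=float(p),
                )
            )
        return out

    def simple_effects(
        self, by: Optional[str] = None, correction: Correction = "auto"
    ) -> dict[object, tuple[AnovaResult, list[PosthocResult]]]:
        """One-way RM-ANOVA of the other factor at each level of ``by``.

        Each level uses its own error term (no pooling across levels).
        """
        if len(self.model.within) != 2:
            raise ValueError("simple effects need a two-factor model")
        by = by or self.model.within[1]
        by_axis = self.model.within.index(by)
        other_axis = 1 - by_axis
        other = self.model.within[other_axis]
        out: dict[object, tuple[AnovaResult, list[PosthocResult]]] = {}
        for li, level in enumerate(self.model.levels[by_axis]):
            sub = np.take(self.model.Y, li, axis=by_axis + 1)
            res = _fit_oneway(sub, other, correction)
            sub_model = RepeatedMeasuresAnova.__new__(RepeatedMeasuresAnova)
            sub_model.dv = self.model.dv
            sub_model.within = (other,)
            sub_model.subject = self.model.subject
            sub_model.subjects = self.model.subjects
            sub_model.levels = (self.model.levels[other_axis],)
            sub_model.Y = sub
            out[level] = (res, RMAnovaResults(sub_model, [res]).posthoc(other))
        return out

    def plot_cell_means(self, ax=None):
        """Interaction plot of cell means (two-factor models only)."""
        import matplotlib.pyplot as plt

        if len(self.model.within) != 2:
            raise ValueError("cell-means plot needs a two-factor model")
        if ax is None:
            _, ax = plt.subplots()
        means = self.model.Y.mean(axis=0)
        xs = self.model.levels[1]
        for i, lev in enumerate(self.model.levels[0]):
            ax.plot(xs, means[i], marker="o", label=str(lev))
        ax.set_xlabel(self.model.within[1])
        ax.set_ylabel(self.model.dv)
        ax.legend(title=self.model.within[0])
        return ax


def rm_anova_2way(
    table: CohortTable, outcome: str, correction: Correction = "auto"
) -> list[AnovaResult]:
    """Two-way (game × height) within-subject ANOVA on a cohort table."""
    return RepeatedMeasuresAnova.from_cohort(table, outcome).fit(correction).effects


def lsd_posthoc(table: CohortTable, outcome: str, factor: str) -> list[PosthocResult]:
    """LSD pairwise comparisons of one factor's marginal means."""
    return RepeatedMeasuresAnova.from_cohort(table, outcome).fit().posthoc(factor)


def simple_effects(
    table: CohortTable, outcome: str, by: str = "theta"
) -> dict[object, tuple[AnovaResult, list[PosthocResult]]]:
    """Per-height (or per-game) one-way RM-ANOVA with its own LSD pairs."""
    return RepeatedMeasuresAnova.from_cohort(table, outcome).fit().simple_effects(by=by)


def simulate_null_type1(
    n_subjects: int = 31,
    a: int = 3,
    b: int = 4,
    reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    correction: Correction = "auto",
) -> dict[str, float]:
    """Monte-Carlo type-I error of the two-way RM-ANOVA under a spherical null.

    Tables are subject random intercept (SD 1) plus i.i.d. unit-normal noise —
    no condition effects, compound-symmetric hence spherical covariance.
    Returns the per-effect rejection rate at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    names = ("A", "B", "A*B")
    rejections = dict.fromkeys(names, 0)
    for _ in range(reps):
        Y = rng.normal(size=(n_subjects, 1, 1)) + rng.normal(size=(n_subjects, a, b))
        for res in _fit_twoway(Y, ("A", "B"), correction):
            if res.p < alpha:
                rejections[res.effect] += 1
    return {k: v / reps for k, v in rejections.items()}
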