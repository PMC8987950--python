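"""Within-subject ANOVA battery vs. independent oracles."""

import numpy as np
import pandas as pd
import pytest

from oracles import brute_force_f

from gradedreach.kinematics import CohortTable
from gradedreach.rmstats import (
    RepeatedMeasuresAnova,
    classify_effect_size,
    eta_sq_from_f,
    shapiro_wilk,
    simulate_null_type1,
)


def long_table(Y, games=None, thetas=None):
    n, a, b = Y.shape
    games = games or [f"g{j}" for j in range(a)]
    thetas = thetas or list(range(b))
    rows = [
        {"participant": f"S{i}", "game": games[j], "theta": thetas[k], "y": Y[i, j, k]}
        for i in range(n)
        for j in range(a)
        for k in range(b)
    ]
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_brute_force_oracle(self, rng):
        Y = rng.normal(size=(5, 3, 4)) + rng.normal(size=(5, 1, 1))
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit(
            correction="never"
        )
        oracle = brute_force_f(Y)
        for effect, key in [("game", "A"), ("theta", "B"), ("game*theta", "AB")]:
            e = res.effect(effect)
            F, df1, df2, p, eta = oracle[key]
            assert e.F == pytest.approx(F, abs=1e-10)
            assert (e.df1, e.df2) == (df1, df2)
            assert e.p == pytest.approx(p, abs=1e-10)
            assert e.partial_eta_sq == pytest.approx(eta, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(9, 3, 4))
        df = long_table(Y)
        res = RepeatedMeasuresAnova(df, "y", ("game", "theta")).fit(correction="never")
        aov = pg.rm_anova(
            data=df, dv="y", within=["game", "theta"], subject="participant",
            detailed=True,
        ).set_index("Source")
        for effect, src in [("game", "game"), ("theta", "theta"),
                            ("game*theta", "game * theta")]:
            e = res.effect(effect)
            assert e.F == pytest.approx(float(aov.loc[src, "F"]), abs=1e-9)
            assert e.p == pytest.approx(float(aov.loc[src, "p_unc"]), abs=1e-9)

    def test_flat_table_gives_zero_f(self):
        Y = np.ones((6, 3, 4)) * 3.3
        Y += np.arange(6)[:, None, None]  # subject offsets only
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit()
        for e in res:
            assert e.F == 0.0 and e.p == 1.0 and e.partial_eta_sq == 0.0

    def test_eta_identity_with_f(self, rng):
        Y = rng.normal(size=(8, 3, 4)) + np.linspace(0, 1, 4)
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit(
            correction="never"
        )
        for e in res:
            assert eta_sq_from_f(e.F, e.df1, e.df2) == pytest.approx(
                e.partial_eta_sq, abs=1e-12
            )

    def test_incomplete_design_rejected(self, rng):
        Y = rng.normal(size=(4, 3, 4))
        df = long_table(Y).iloc[:-1]
        with pytest.raises(ValueError):
            RepeatedMeasuresAnova(df, "y", ("game", "theta"))

    def test_two_subjects_minimum(self, rng):
        df = long_table(rng.normal(size=(1, 3, 4)))
        with pytest.raises(ValueError):
            RepeatedMeasuresAnova(df, "y", ("game", "theta"))


class TestSphericity:
    def test_epsilon_one_for_two_level_factor(self, rng):
        Y = rng.normal(size=(10, 2))
        df = pd.DataFrame(
            [
                {"participant": i, "game": f"g{j}", "y": Y[i, j]}
                for i in range(10)
                for j in range(2)
            ]
        )
        e = RepeatedMeasuresAnova(df, "y", "game").fit().effects[0]
        assert e.epsilon_gg == 1.0

    def test_epsilon_bounds_on_random_covariances(self, rng):
        for _ in range(30):
            k = int(rng.integers(3, 6))
            A = rng.normal(size=(k, k))
            cov = A @ A.T + k * np.eye(k)
            Y = rng.multivariate_normal(np.zeros(k), cov, size=20)
            df = pd.DataFrame(
                [
                    {"participant": i, "game": f"g{j}", "y": Y[i, j]}
                    for i in range(20)
                    for j in range(k)
                ]
            )
            e = RepeatedMeasuresAnova(df, "y", "game").fit().effects[0]
            assert 1.0 / (k - 1) - 1e-12 <= e.epsilon_gg <= 1.0 + 1e-12

    def test_epsilon_approaches_one_under_compound_symmetry(self, rng):
        # CS covariance is spherical after contrasts: eps -> 1 as n grows
        n, k = 400, 4
        subj = rng.normal(size=(n, 1)) * 2.0
        Y = subj + rng.normal(size=(n, k))
        df = pd.DataFrame(
            [
                {"participant": i, "game": f"g{j}", "y": Y[i, j]}
                for i in range(n)
                for j in range(k)
            ]
        )
        e = RepeatedMeasuresAnova(df, "y", "game").fit().effects[0]
        assert e.epsilon_gg > 0.95

    def test_matches_pingouin_mauchly_and_epsilon(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(15, 4)) * np.array([1.0, 1.5, 3.0, 0.5])
        df = pd.DataFrame(
            [
                {"participant": i, "game": f"g{j}", "y": Y[i, j]}
                for i in range(15)
                for j in range(4)
            ]
        )
        e = RepeatedMeasuresAnova(df, "y", "game").fit().effects[0]
        sph = pg.sphericity(df, dv="y", within="game", subject="participant")
        eps = pg.epsilon(df, dv="y", within="game", subject="participant",
                         correction="gg")
        assert e.mauchly_p == pytest.approx(float(sph.pval), abs=1e-9)
        assert e.epsilon_gg == pytest.approx(float(eps), abs=1e-9)

    def test_gg_correction_shrinks_dfs(self, rng):
        Y = rng.normal(size=(15, 4)) * np.array([1.0, 1.0, 5.0, 0.2])
        df = pd.DataFrame(
            [
                {"participant": i, "game": f"g{j}", "y": Y[i, j]}
                for i in range(15)
                for j in range(4)
            ]
        )
        e = RepeatedMeasuresAnova(df, "y", "game").fit(correction="always").effects[0]
        assert e.corrected
        assert e.df1 < 3 and e.df2 < 42


class TestPosthocAndSimpleEffects:
    def test_identical_conditions_give_zero_diff_p_one(self):
        Y = np.tile(np.arange(6)[:, None, None], (1, 3, 4)).astype(float)
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit()
        for pair in res.posthoc("game"):
            assert pair.mean_diff == 0.0 and pair.p == 1.0

    def test_antisymmetric_differences(self, rng):
        Y = rng.normal(size=(8, 3, 4))
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit()
        pairs = {(p.level_a, p.level_b): p.mean_diff for p in res.posthoc("game")}
        M = Y.mean(axis=2)
        for (la, lb), diff in pairs.items():
            ja, jb = int(la[1]), int(lb[1])
            assert diff == pytest.approx(float((M[:, ja] - M[:, jb]).mean()), abs=1e-12)

    def test_shifted_condition_detected(self, rng):
        Y = rng.normal(size=(20, 3, 4))
        Y[:, 2, :] += 2.0  # strong shift on one game
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit()
        pairs = res.posthoc("game")
        hit = [p for p in pairs if "g2" in (p.level_a, p.level_b)]
        assert all(p.p < 0.01 for p in hit)

    def test_simple_effects_match_one_way_subtables(self, rng):
        Y = rng.normal(size=(10, 3, 4))
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit()
        se = res.simple_effects(by="theta", correction="never")
        assert set(se.keys()) == {0, 1, 2, 3}
        for k, (eff, pairs) in se.items():
            sub = long_table(Y[:, :, [k]])
            one = RepeatedMeasuresAnova(
                sub[sub.theta == 0], "y", "game"
            ).fit(correction="never").effects[0]
            assert eff.F == pytest.approx(one.F, abs=1e-10)
            assert eff.p == pytest.approx(one.p, abs=1e-10)
            assert len(pairs) == 3

    def test_effect_injected_at_one_height_found_only_there(self, rng):
        Y = rng.normal(size=(25, 3, 4), scale=0.5)
        Y[:, 0, 3] += 1.5  # game effect only at the last height
        res = RepeatedMeasuresAnova(long_table(Y), "y", ("game", "theta")).fit()
        se = res.simple_effects(by="theta")
        assert se[3][0].p < 0.001
        assert all(se[k][0].p > 0.01 for k in (0, 1, 2))


class TestShapiroAndEffectSize:
    def test_w_bounded(self, rng):
        W, p = shapiro_wilk(rng.normal(size=31))
        assert 0 < W <= 1

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_skewed_samples_rejected_often(self, rng):
        rejections = sum(
            shapiro_wilk(rng.exponential(size=31))[1] < 0.05 for _ in range(200)
        )
        assert rejections / 200 > 0.5

    def test_null_calibration(self, rng):
        rejections = sum(
            shapiro_wilk(rng.normal(size=31))[1] < 0.05 for _ in range(1000)
        )
        assert 0.02 <= rejections / 1000 <= 0.08

    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [
            (17.002, 2, 48, 0.415),
            (2.739, 2, 48, 0.102),
            (22.092, 2.9, 69.7, 0.479),
            (29.704, 3, 72, 0.553),
            (150.701, 3.8, 91.0, 0.863),
            (16.653, 1.6, 37.8, 0.41),
        ],
    )
    def test_eta_sq_reproduces_published_values(self, F, df1, df2, expected):
        ndigits = len(str(expected).split(".")[1])
        assert round(eta_sq_from_f(F, df1, df2), ndigits) == expected

    def test_eta_zero_for_zero_f(self):
        assert eta_sq_from_f(0.0, 2, 48) == 0.0

    @pytest.mark.parametrize(
        "value,label",
        [(0.821, "strong"), (0.25, "small"), (0.30, "moderate"),
         (0.64, "moderate"), (0.0, "small"), (1.0, "strong")],
    )
    def test_effect_size_bands(self, value, label):
        assert classify_effect_size(value) == label

    def test_effect_size_domain(self):
        with pytest.raises(ValueError):
            classify_effect_size(1.2)


def test_null_type1_error_quick():
    """Sanity-size null calibration; the full 2000-rep run lives in the
    acceptance suite."""
    rates = simulate_null_type1(n_subjects=31, reps=300, seed=11)
    for rate in rates.values():
        assert 0.02 <= rate <= 0.09
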