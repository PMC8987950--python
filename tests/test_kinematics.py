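"""Savitzky-Golay pipeline, analysis windows, screening and aggregation."""

import numpy as np
import pytest

from gradedreach import (
    FilterSpec,
    TrialMetrics,
    TrialRecording,
    aggregate,
    analysis_window,
    compute_metrics,
    compute_target,
    screen_trial,
    sg_smooth_diff,
    synthesize_trial,
)
from gradedreach.synthesis import ParticipantModel
from gradedreach.protocol import TrialPlanItem


def make_recording(lumbar, cue=1.0, contact=1.8, hand_x=None, **kw):
    n = len(lumbar)
    t = np.arange(n) / 100.0
    return TrialRecording(
        t=t,
        lumbar_flexion=np.asarray(lumbar, float),
        hand_x=np.asarray(hand_x, float) if hand_x is not None else np.zeros(n),
        hand_z=np.ones(n),
        cue_time=cue,
        contact_time=contact,
        game="reachality",
        theta=30.0,
        hand="right",
        **kw,
    )


class TestSavitzkyGolay:
    def test_cubic_derivative_exact_in_interior(self):
        t = np.arange(0, 3, 0.01)
        y = 2 * t**3 - t
        _, dy = sg_smooth_diff(y)
        expected = 6 * t**2 - 1
        interior = slice(20, -20)
        assert np.max(np.abs(dy[interior] - expected[interior])) <= 1e-8

    def test_constant_series_untouched(self):
        y = np.full(200, 7.5)
        sm, dy = sg_smooth_diff(y)
        assert np.allclose(sm, 7.5, atol=1e-12)
        assert np.allclose(dy, 0.0, atol=1e-10)

    def test_sine_derivative_under_one_percent(self):
        # interior only: mirror padding cannot extend a non-symmetric sine,
        # so the half-window at each edge is excluded from the comparison
        t = np.arange(0, 2, 0.01)
        y = np.sin(2 * np.pi * t)  # 1 Hz at 100 Hz sampling
        _, dy = sg_smooth_diff(y)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        interior = slice(20, -20)
        err = np.max(np.abs(dy[interior] - expected[interior]))
        assert err / np.max(np.abs(expected)) < 0.01

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sg_smooth_diff(np.zeros(40))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FilterSpec(window=40)
        with pytest.raises(ValueError):
            FilterSpec(window=5, polyorder=5)


class TestAnalysisWindow:
    def test_contact_plus_200ms(self):
        rec = make_recording(np.zeros(300), cue=1.0, contact=1.8)
        assert analysis_window(rec) == (1.0, 2.0)

    def test_clipped_to_recording_end(self):
        rec = make_recording(np.zeros(190), cue=1.0, contact=1.89)
        t0, t1 = analysis_window(rec)
        assert t1 == pytest.approx(1.89)

    def test_missed_trial_ends_at_peak_forward_displacement(self):
        hand_x = np.concatenate([np.linspace(0, 0.8, 150), np.linspace(0.8, 0.6, 150)])
        rec = make_recording(np.zeros(300), cue=0.5, contact=None, hand_x=hand_x)
        t0, t1 = analysis_window(rec)
        assert t0 == 0.5
        assert t1 == pytest.approx(1.49)  # argmax of hand_x

    def test_no_cue_invalid(self):
        rec = make_recording(np.zeros(300))
        rec.cue_time = float("nan")
        with pytest.raises(ValueError):
            analysis_window(rec)


class TestMetrics:
    def noise_free_trial(self, anthro, A=40.0, T=1.0):
        pm = ParticipantModel(
            anthro=anthro, lumbar_share=1.0, reaction_time=0.25,
            movement_time=T, speed_gain={"reachality": 1.0}, noise_sd=0.0,
        )
        item = TrialPlanItem(
            game="reachality", event_kind="reach", theta=A, hand="right",
            set_index=0, trial_index=0, rest_after=0.0,
        )
        return synthesize_trial(item, pm, compute_target(anthro, A), seed=0)

    def test_noise_free_min_jerk_recovery(self, anthro):
        rec = self.noise_free_trial(anthro)
        m = compute_metrics(rec)
        assert m.lumbar_excursion_deg == pytest.approx(40.0, abs=0.5)
        assert m.peak_lumbar_velocity_deg_s == pytest.approx(75.0, rel=0.02)

    def test_impact_at_target(self, anthro):
        rec = self.noise_free_trial(anthro)
        m = compute_metrics(rec)
        tp = compute_target(anthro, 40.0)
        assert m.impact_ap_m == pytest.approx(tp.anterior, abs=0.01)
        assert m.impact_vertical_m == pytest.approx(tp.vertical, abs=0.01)

    def test_offset_invariance(self, anthro):
        rec = self.noise_free_trial(anthro)
        m0 = compute_metrics(rec)
        rec.lumbar_flexion = rec.lumbar_flexion + 13.7
        m1 = compute_metrics(rec)
        assert m1.lumbar_excursion_deg == pytest.approx(m0.lumbar_excursion_deg, abs=1e-9)
        assert m1.peak_lumbar_velocity_deg_s == pytest.approx(
            m0.peak_lumbar_velocity_deg_s, abs=1e-9
        )

    def test_net_excursion_mode(self, anthro):
        rec = self.noise_free_trial(anthro)
        m = compute_metrics(rec, excursion_mode="net")
        # flex-and-hold: net change equals peak-minus-onset here
        assert m.lumbar_excursion_deg == pytest.approx(40.0, abs=0.5)

    def test_static_posture_screened_out(self):
        rec = make_recording(np.zeros(300))
        m = screen_trial(compute_metrics(rec))
        assert not m.included and m.exclusion_reason == "no_lumbar_motion"


class TestScreening:
    def metrics(self, excursion, missed=False):
        return TrialMetrics(
            lumbar_excursion_deg=excursion, peak_lumbar_velocity_deg_s=10.0,
            impact_ap_m=0.5, impact_vertical_m=1.0, missed=missed,
        )

    def test_small_excursion_excluded(self):
        assert not screen_trial(self.metrics(0.3)).included

    def test_missed_catch_with_reaction_retained(self):
        assert screen_trial(self.metrics(25.0, missed=True)).included

    def test_zero_threshold_includes_everything(self):
        assert screen_trial(self.metrics(0.0), min_excursion=0.0).included


class TestAggregate:
    def metric(self, participant, game, theta, hand="right", value=10.0,
               included=True, kind="reach"):
        return TrialMetrics(
            lumbar_excursion_deg=value, peak_lumbar_velocity_deg_s=2 * value,
            impact_ap_m=0.5, impact_vertical_m=1.0, included=included,
            participant=participant, game=game, theta=theta, hand=hand,
            event_kind=kind,
        )

    def test_cell_mean_of_identical_trials(self):
        ms = [self.metric("P1", "reachality", 15.0, value=12.0) for _ in range(5)]
        table = aggregate(ms)
        assert len(table.data) == 1
        assert table.data.loc[0, "lumbar_excursion_deg"] == 12.0

    def test_left_hand_trials_dropped(self):
        ms = [
            self.metric("P1", "reachality", 15.0, hand="right", value=10.0),
            self.metric("P1", "reachality", 15.0, hand="left", value=99.0),
        ]
        table = aggregate(ms)
        assert table.data.loc[0, "lumbar_excursion_deg"] == 10.0

    def test_ducks_dropped(self):
        ms = [
            self.metric("P1", "fishality", 15.0, hand=None),
            TrialMetrics(0.0, 0.0, float("nan"), float("nan"),
                         participant="P1", game="fishality", theta=None,
                         hand=None, event_kind="duck"),
        ]
        assert len(aggregate(ms).data) == 1

    def test_excluded_trials_not_averaged(self):
        ms = [
            self.metric("P1", "reachality", 15.0, value=10.0),
            self.metric("P1", "reachality", 15.0, value=50.0, included=False),
        ]
        assert aggregate(ms).data.loc[0, "lumbar_excursion_deg"] == 10.0

    def test_missing_cell_reported(self):
        ms = [
            self.metric("P1", "reachality", 15.0),
            self.metric("P1", "reachality", 30.0),
            self.metric("P2", "reachality", 15.0),
        ]
        table = aggregate(ms)
        assert ("P2", "reachality", 30.0) in table.incomplete
        assert not table.complete
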