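"""Event detection and per-trial outcome measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from gaitprop.events import (
    NoEventsError,
    detect_events_kinematic,
    detect_events_kinetic,
    peak_agrf,
    sla,
    step_length_at_fs,
    summarize_trial,
)
from gaitprop.preprocess import select_window


class TestKineticDetection:
    def test_single_square_pulse_gives_one_stance(self):
        t = np.arange(0, 2, 0.001)
        v = np.where((t >= 0.5) & (t < 1.2), 400.0, 0.0)
        ev = detect_events_kinetic(t, v)
        assert len(ev.fs_times) == len(ev.to_times) == 1
        assert ev.fs_times[0] == pytest.approx(0.5, abs=1e-3)
        assert ev.to_times[0] == pytest.approx(1.2, abs=1e-3)

    def test_constant_force_never_crosses(self):
        t = np.arange(0, 2, 0.001)
        with pytest.raises(NoEventsError):
            detect_events_kinetic(t, np.full_like(t, 500.0))

    def test_noiseless_trial_recovers_all_stances(self, noiseless_trial):
        trial, truth = noiseless_trial
        sel = select_window(trial)
        a, b = sel.window_used
        ev = detect_events_kinetic(sel.trial.kinetic_time, sel.trial.vgrf_left)
        fs_true = truth.fs_times["paretic"]
        fs_true = fs_true[(fs_true >= a) & (fs_true < b)]
        assert len(ev.fs_times) >= 10
        np.testing.assert_allclose(
            ev.fs_times[: len(fs_true)], fs_true[: len(ev.fs_times)], atol=1e-3
        )

    def test_subdebounce_dip_is_ignored(self):
        t = np.arange(0, 2, 0.001)
        v = np.where((t >= 0.5) & (t < 1.2), 400.0, 0.0)
        v[(t >= 0.8) & (t < 0.82)] = 50.0  # 20 ms dip below threshold
        ev = detect_events_kinetic(t, v, debounce=0.05)
        assert len(ev.fs_times) == 1  # still a single stance

    def test_interpolated_crossing_is_subsample(self):
        t = np.arange(0, 1, 0.001)
        v = np.clip((t - 0.5) * 4000.0, 0.0, 400.0)  # ramp crosses 100 N at 0.525
        ev = detect_events_kinetic(t, np.where(t < 0.9, v, 0.0))
        assert ev.fs_times[0] == pytest.approx(0.525, abs=1e-6)


class TestKinematicDetection:
    def test_sinusoid_events_at_crests_and_troughs(self):
        t = np.arange(0, 10, 0.01)
        x = 0.3 * np.sin(2 * np.pi * 1.0 * t)
        ev = detect_events_kinematic(t, x, expected_stride_time=1.0)
        crests = 0.25 + np.arange(10)
        assert len(ev.fs_times) >= 8
        for ft in ev.fs_times:
            assert np.min(np.abs(crests - ft)) < 0.011
        assert np.all(ev.to_times > ev.fs_times)

    def test_constant_channel_has_no_events(self):
        t = np.arange(0, 5, 0.01)
        with pytest.raises(NoEventsError):
            detect_events_kinematic(t, np.full_like(t, 0.2))

    def test_noiseless_trial_within_one_kinematic_sample(self, noiseless_trial):
        trial, truth = noiseless_trial
        sel = select_window(trial)
        a, b = sel.window_used
        ev = detect_events_kinematic(sel.trial.kinematic_time, sel.trial.malleolus_ap_right)
        fs_true = truth.fs_times["nonparetic"]
        fs_true = fs_true[(fs_true >= a) & (fs_true < b)]
        np.testing.assert_allclose(
            ev.fs_times[: len(fs_true)], fs_true[: len(ev.fs_times)], atol=1e-2
        )


class TestStepLength:
    def test_leading_minus_trailing(self):
        t = np.array([0.0, 0.01, 0.02])
        left = np.array([0.30, 0.30, 0.30])
        right = np.array([-0.25, -0.25, -0.25])
        assert step_length_at_fs(t, left, right, 0.01, "left") == pytest.approx(0.55)
        assert step_length_at_fs(t, left, right, 0.01, "right") == pytest.approx(-0.55)

    def test_coincident_malleoli_give_zero(self):
        t = np.array([0.0, 0.01])
        x = np.array([0.1, 0.1])
        assert step_length_at_fs(t, x, x, 0.0, "left") == 0.0

    def test_fs_outside_span_rejected(self):
        t = np.array([0.0, 0.01])
        with pytest.raises(ValueError):
            step_length_at_fs(t, t, t, 5.0, "left")


class TestPeakAgrf:
    def test_half_sine_amplitude_recovered(self):
        t = np.arange(0, 1, 0.001)
        ap = 80.0 * np.sin(np.pi * np.clip((t - 0.2) / 0.4, 0, 1))
        peak, flagged = peak_agrf(t, ap, 0.2, 0.6)
        assert peak == pytest.approx(80.0, abs=1e-6)
        assert not flagged

    def test_all_braking_stance_flagged(self):
        t = np.arange(0, 1, 0.001)
        peak, flagged = peak_agrf(t, -50.0 * np.ones_like(t), 0.2, 0.6)
        assert peak <= 0.0
        assert flagged

    def test_empty_stance_rejected(self):
        t = np.arange(0, 1, 0.001)
        with pytest.raises(ValueError):
            peak_agrf(t, t, 0.6, 0.2)


class TestSla:
    def test_symmetric_is_zero(self):
        assert sla(0.50, 0.50) == 0.0

    def test_hand_computed_example(self):
        assert sla(0.55, 0.45) == pytest.approx(0.10)
        assert sla(0.45, 0.55) == pytest.approx(-0.10)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError):
            sla(0.0, 0.0)

    @settings(max_examples=200, derandomize=True)
    @given(
        p=hst.floats(min_value=1e-3, max_value=2.0),
        q=hst.floats(min_value=1e-3, max_value=2.0),
    )
    def test_bounded_antisymmetric_zero_iff_equal(self, p, q):
        v = sla(p, q)
        assert -1.0 < v < 1.0
        assert sla(q, p) == pytest.approx(-v, abs=1e-12)
        if p == q:
            assert v == 0.0
        else:
            assert (v > 0) == (p > q)


def test_summarize_trial_binds_metrics_to_event_sources(noiseless_trial):
    trial, truth = noiseless_trial
    m = summarize_trial(select_window(trial).trial, paretic_side=truth.paretic_side)
    assert m.mean_step_length_paretic == pytest.approx(truth.step_lengths["paretic"], abs=1e-9)
    assert m.mean_agrf_nonparetic == pytest.approx(truth.agrf_peaks["nonparetic"], abs=1e-9)
    assert m.n_steps_paretic >= 10 and m.n_steps_nonparetic >= 10
    # cross-method consistency: kinetic and kinematic foot-strikes within 30 ms
    kin = m.extras["kinematic_events"]["paretic"]
    kit = m.extras["kinetic_events"]["paretic"]
    n = min(len(kin.fs_times), len(kit.fs_times))
    assert np.max(np.abs(kin.fs_times[:n] - kit.fs_times[:n])) < 0.03
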