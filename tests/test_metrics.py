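"""Spatiotemporal metric exactness on constructed fixtures."""

import numpy as np
import pytest

import synergait as sg
from synergait import metrics as mm
from synergait.types import BeamGeometry, GaitEvents, TrialMeta, TrialRecording


def _hold_track(t, hs, values):
    """Zero-order hold: marker equals the most recent placement."""
    idx = np.clip(np.searchsorted(hs, t, side="right") - 1, 0, len(values) - 1)
    return np.asarray(values, dtype=float)[idx]


def _make_trial(right_ml, left_ml, foot_width=0.10, beam=None, fs=50.0,
                n_strides=None, trunk_ml=None):
    """Trial with scripted per-placement foot ML positions, 1 s strides."""
    n = len(right_ml) - 1
    right_hs = np.arange(len(right_ml), dtype=float)
    left_hs = right_hs[:-1] + 0.5
    dur = right_hs[-1] + 0.5
    t = np.arange(0.0, dur, 1.0 / fs)
    markers = {}
    if trunk_ml is None:
        trunk_ml = np.zeros_like(t)
    markers["trunk"] = np.column_stack([trunk_ml, np.zeros_like(t), np.ones_like(t)])
    for leg, hs, vals in (("l", left_hs, left_ml), ("r", right_hs, right_ml)):
        ml = _hold_track(t, hs, vals)
        psi = np.interp(t, hs, np.arange(len(hs)))
        ap = 0.3 * np.cos(2 * np.pi * (psi - np.floor(psi)))
        ref = np.column_stack([ml, ap, np.zeros_like(t)])
        markers[f"foot_{leg}"] = ref
        sgn = 1.0 if leg == "l" else -1.0
        markers[f"foot_{leg}_med"] = ref + np.array([sgn * foot_width / 2, 0, 0])
        markers[f"foot_{leg}_lat"] = ref + np.array([-sgn * foot_width / 2, 0, 0])
    cop = np.column_stack([np.zeros_like(t), np.zeros_like(t)])
    trial = TrialRecording(
        emg=np.ones((11, int(dur * 2000))) * 1e-6, fs_emg=2000.0,
        markers=markers, fs_kin=fs, cop=cop, fs_cop=fs,
        beam=beam, meta=TrialMeta("S", "Pre", "narrow" if beam else "normal"),
    )
    events = GaitEvents(left=left_hs, right=right_hs, fs_kin=fs)
    return trial, events, (n if n_strides is None else n_strides)


class TestStepWidth:
    def test_fixed_feet(self):
        trial, events, n = _make_trial([0.05] * 9, [-0.05] * 8)
        mean, sd = mm.step_width(trial, events, n)
        assert mean == pytest.approx(0.10)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_alternating_widths_enumerated(self):
        # left fixed at 0; right alternates 0.08 / 0.12 each stride
        right = [0.08, 0.12] * 5
        trial, events, n = _make_trial(right, [0.0] * 9)
        mean, sd = mm.step_width(trial, events, n)
        # brute-force enumeration of the step sequence
        widths = []
        last = {"right": None, "left": None}
        placements = sorted(
            [(t, "right", v) for t, v in zip(np.arange(10.0), right)]
            + [(t + 0.5, "left", 0.0) for t in np.arange(9.0)])
        for t, leg, v in placements:
            other = "left" if leg == "right" else "right"
            if last[other] is not None:
                widths.append(abs(v - last[other]))
            last[leg] = v
        # restrict to steps inside the analyzed strides, as the metric does
        assert mean == pytest.approx(np.mean(widths), abs=1e-3)
        assert sd == pytest.approx(np.std(widths), abs=1e-3)

    def test_narrow_narrower_than_normal(self):
        gt_n = sg.make_ground_truth(n_strides=15, lead_in=2, step_width_mean=0.12, seed=1)
        gt_b = sg.make_ground_truth(n_strides=15, lead_in=2, step_width_mean=0.05, seed=1)
        rows = {}
        for name, gt in (("normal", gt_n), ("narrow", gt_b)):
            tr = sg.gen_trial(gt, TrialMeta("S", "Pre", "normal"), include_emg=False)
            tr = sg.trim_initial(tr, 2.0)
            events = sg.detect_events(tr)
            rows[name], _ = mm.step_width(tr, events, 12)
        assert rows["narrow"] < rows["normal"]


class TestBeamScoring:
    BEAM = BeamGeometry(0.0, 0.12)

    def test_inside_beam_zero_error_and_full_pct(self):
        # foot centers at +-1 cm, width 10 cm -> edges within +-6 cm
        trial, events, n = _make_trial([0.01] * 7, [-0.01] * 6, beam=self.BEAM)
        assert mm.foot_placement_error(trial, events, n) == pytest.approx(0.0)
        assert mm.pct_steps_in_beam(trial, events, n) == pytest.approx(100.0)

    def test_two_cm_overshoot(self):
        # lateral edge at 0.03 + 0.05 = 0.08 -> 2 cm beyond the 0.06 edge
        trial, events, n = _make_trial([0.03] * 7, [-0.03] * 6, beam=self.BEAM)
        assert mm.foot_placement_error(trial, events, n) == pytest.approx(0.02)
        assert mm.pct_steps_in_beam(trial, events, n) == pytest.approx(0.0)

    def test_half_inside_half_one_cm_out(self):
        right = [0.0, 0.02] * 4  # alternate inside / 1 cm overshoot
        left = [0.0, -0.02] * 4
        trial, events, n = _make_trial(right, left[:-1], beam=self.BEAM)
        err = mm.foot_placement_error(trial, events, n)
        assert err == pytest.approx(0.005, abs=5e-4)
        pct = mm.pct_steps_in_beam(trial, events, n)
        assert pct == pytest.approx(50.0, abs=5.0)

    def test_counting_fixture(self):
        # 3 of 12 placements inside -> 25%
        right = [0.0, 0.03, 0.03, 0.03] * 2  # placements at strides
        left = [-0.03, -0.03, 0.0, -0.03, -0.03, -0.03, 0.0]
        trial, events, n = _make_trial(right, left, beam=self.BEAM)
        assert mm.pct_steps_in_beam(trial, events, n) == pytest.approx(
            100.0 * 4 / 15, abs=2.0)

    def test_beam_required(self):
        trial, events, n = _make_trial([0.05] * 5, [-0.05] * 4)
        with pytest.raises(ValueError, match="beam"):
            mm.foot_placement_error(trial, events, n)


class TestTrunkCoM:
    def test_sinusoid_closed_forms(self):
        a, T, fs = 0.03, 1.0, 200.0
        t = np.arange(0, 8, 1 / fs)
        ml = a * np.sin(2 * np.pi * t / T)
        strides = [(i * T, (i + 1) * T) for i in range(7)]
        disp_mean, disp_sd, vel_mean = mm.trunk_com_metrics(ml, fs, strides)
        assert disp_mean == pytest.approx(2 * a, rel=1e-3)
        assert disp_sd == pytest.approx(0.0, abs=1e-6)
        assert vel_mean == pytest.approx(4 * a / T, rel=5e-3)

    def test_alternating_amplitude_sd(self):
        T, fs = 1.0, 200.0
        t = np.arange(0, 8, 1 / fs)
        amp = np.where((t // T).astype(int) % 2 == 0, 0.02, 0.03)
        ml = amp * np.sin(2 * np.pi * t / T)
        strides = [(i * T, (i + 1) * T) for i in range(8)]
        disp_mean, disp_sd, _ = mm.trunk_com_metrics(ml, fs, strides)
        assert disp_mean == pytest.approx(0.05, rel=1e-3)
        assert disp_sd == pytest.approx(0.01, rel=2e-2)


def test_translation_invariance():
    beam = BeamGeometry(0.0, 0.12)
    trial, events, n = _make_trial([0.03, 0.0, 0.05] * 3, [-0.02] * 8,
                                   beam=beam)
    base = mm.gait_metrics(trial, events, n_strides=n)
    shift = 0.37
    markers = {k: v + np.array([shift, 0, 0]) for k, v in trial.markers.items()}
    moved = TrialRecording(
        emg=trial.emg, fs_emg=trial.fs_emg, markers=markers,
        fs_kin=trial.fs_kin, cop=trial.cop + [shift, 0], fs_cop=trial.fs_cop,
        beam=BeamGeometry(shift, 0.12), meta=trial.meta)
    other = mm.gait_metrics(moved, events, n_strides=n)
    for key, val in base.as_dict().items():
        assert other.as_dict()[key] == pytest.approx(val, abs=1e-12), key


def test_generator_parameters_recovered(small_trial, small_events, small_gt):
    trimmed = sg.trim_initial(small_trial, 5.0)
    row = mm.gait_metrics(trimmed, small_events, n_strides=40)
    assert row.step_width_mean == pytest.approx(0.12, abs=0.01)
    assert row.n_strides == 40
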