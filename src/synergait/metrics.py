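"""Spatiotemporal and trunk-CoM outcome measures per trial.

All positions are mediolateral (ML) coordinates in meters. Foot placement is
read from the foot reference marker at the heel-strike instant; beam scoring
uses the medial/lateral edge markers. Every metric is invariant to a
constant ML translation of the whole scene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import GaitEvents, TrialRecording


def _ml_at(times: np.ndarray, trial: TrialRecording, marker: str) -> np.ndarray:
    t_kin = trial.marker_time()
    return np.interp(times, t_kin, trial.markers[marker][:, 0])


def _placements(trial: TrialRecording, events: GaitEvents,
                n_strides: Optional[int]) -> list[tuple[float, str, float]]:
    """(time, leg, foot ML) for every heel-strike within the used strides."""
    strides = events.strides(n_strides)
    t_lo, t_hi = strides[0][0], strides[-1][1]
    out = []
    for t, leg in events.labeled():
        if t_lo <= t <= t_hi:
            ml = float(_ml_at(np.array([t]), trial, f"foot_{leg[0]}")[0])
            out.append((t, leg, ml))
    return out


def step_width(trial: TrialRecording, events: GaitEvents,
               n_strides: Optional[int] = 160) -> tuple[float, float]:
    """Mean and SD of |ML_left - ML_right| across steps.

    Each new placement is paired with the most recent contralateral
    placement; steps lacking one (trial boundaries) are skipped.
    """
    placements = _placements(trial, events, n_strides)
    last: dict[str, float] = {}
    widths = []
    for _, leg, ml in placements:
        other = "left" if leg == "right" else "right"
        if other in last:
            widths.append(abs(ml - last[other]))
        last[leg] = ml
    if not widths:
        raise ValueError("no step pairs available")
    w = np.asarray(widths)
    return float(w.mean()), float(w.std(ddof=0))


def _edge_positions(trial: TrialRecording, events: GaitEvents,
                    n_strides: Optional[int]) -> list[tuple[float, float]]:
    """(medial edge ML, lateral edge ML) per placement, inner/outer sorted
    toward/away from the beam center."""
    beam = trial.beam
    if beam is None:
        raise ValueError("beam geometry required")
    out = []
    for t, leg, _ in _placements(trial, events, n_strides):
        ts = np.array([t])
        e1 = float(_ml_at(ts, trial, f"foot_{leg[0]}_med")[0])
        e2 = float(_ml_at(ts, trial, f"foot_{leg[0]}_lat")[0])
        out.append((min(e1, e2), max(e1, e2)))
    return out


def foot_placement_error(trial: TrialRecording, events: GaitEvents,
                         n_strides: Optional[int] = 160) -> float:
    """Mean overshoot of the furthest-protruding foot edge beyond the beam.

    Zero when the whole foot is inside the beam; otherwise the ML distance
    from the protruding edge to the nearer beam edge. Mean over steps.
    """
    beam = trial.beam
    if beam is None:
        raise ValueError("foot placement error requires beam geometry (narrow trials)")
    lo, hi = beam.edges
    errs = []
    for e_lo, e_hi in _edge_positions(trial, events, n_strides):
        errs.append(max(0.0, lo - e_lo, e_hi - hi))
    return float(np.mean(errs))


def pct_steps_in_beam(trial: TrialRecording, events: GaitEvents,
                      n_strides: Optional[int] = 160) -> float:
    """Percentage of steps with the whole foot (both edges) inside the beam."""
    beam = trial.beam
    if beam is None:
        raise ValueError("beam geometry required")
    lo, hi = beam.edges
    edges = _edge_positions(trial, events, n_strides)
    eps = 1e-9  # a foot exactly at the beam edge counts as inside
    inside = sum(1 for e_lo, e_hi in edges
                 if e_lo >= lo - eps and e_hi <= hi + eps)
    return 100.0 * inside / len(edges)


def trunk_com_ml(trial: TrialRecording) -> np.ndarray:
    """Trunk CoM ML trajectory = trunk marker-cluster centroid ML."""
    names = [k for k in trial.markers if k.startswith("trunk")]
    return np.mean([trial.markers[k][:, 0] for k in names], axis=0)


def trunk_com_metrics(
    trunk_ml: np.ndarray,
    fs: float,
    strides: list[tuple[float, float]],
) -> tuple[float, float, float]:
    """(mean, SD) of per-stride peak-to-peak ML displacement and mean of
    per-stride mean absolute ML velocity (central differences)."""
    trunk_ml = np.asarray(trunk_ml, dtype=float)
    t = np.arange(trunk_ml.size) / fs
    vel = np.gradient(trunk_ml, 1.0 / fs)
    disps, vels = [], []
    for (t0, t1) in strides:
        sel = (t >= t0) & (t < t1)
        seg = trunk_ml[sel]
        if seg.size < 2:
            continue
        disps.append(np.ptp(seg))
        vels.append(np.mean(np.abs(vel[sel])))
    disps, vels = np.asarray(disps), np.asarray(vels)
    return float(disps.mean()), float(disps.std(ddof=0)), float(vels.mean())


@dataclass
class GaitMetricRow:
    """Per-trial spatiotemporal outcome measures (meters, %, counts)."""

    step_width_mean: float
    step_width_sd: float
    com_disp_mean: float
    com_disp_sd: float
    com_vel_mean: float
    n_strides: int
    fpe_mean: Optional[float] = None     # narrow-base only
    pct_in_beam: Optional[float] = None  # narrow-base only

    def as_dict(self) -> dict[str, float]:
        d = {
            "step_width_mean": self.step_width_mean,
            "step_width_sd": self.step_width_sd,
            "com_disp_mean": self.com_disp_mean,
            "com_disp_sd": self.com_disp_sd,
            "com_vel_mean": self.com_vel_mean,
        }
        if self.fpe_mean is not None:
            d["fpe_mean"] = self.fpe_mean
        if self.pct_in_beam is not None:
            d["pct_in_beam"] = self.pct_in_beam
        return d


def gait_metrics(trial: TrialRecording, events: GaitEvents,
                 n_strides: int = 160) -> GaitMetricRow:
    strides = events.strides(n_strides)
    sw_mean, sw_sd = step_width(trial, events, n_strides)
    ml = trunk_com_ml(trial)
    disp_mean, disp_sd, vel_mean = trunk_com_metrics(ml, trial.fs_kin, strides)
    row = GaitMetricRow(
        step_width_mean=sw_mean, step_width_sd=sw_sd,
        com_disp_mean=disp_mean, com_disp_sd=disp_sd,
        com_vel_mean=vel_mean, n_strides=len(strides),
    )
    if trial.beam is not None:
        row.fpe_mean = foot_placement_error(trial, events, n_strides)
        row.pct_in_beam = pct_steps_in_beam(trial, events, n_strides)
    return row
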