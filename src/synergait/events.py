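"""Gait-event detection from the center of pressure.

Heel-strikes are placed at anterior extrema of the AP CoP component (the
butterfly-diagram geometry of treadmill walking), with a 0.4 s refractory
separation. Because in narrow-base walking both feet share the midline and
the butterfly collapses, events are not lateralized from the CoP: each event
is assigned to the foot whose reference marker is more anterior at that
moment, and alternation is enforced.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .types import GaitEvents, TrialRecording

log = logging.getLogger(__name__)


def trim_initial(trial: TrialRecording, seconds: float = 30.0) -> TrialRecording:
    """Drop the first ``seconds`` of every stream (habituation period)."""
    if trial.duration <= seconds:
        raise ValueError(
            f"trial ({trial.duration:.1f} s) shorter than trim of {seconds} s")
    n_emg = int(round(seconds * trial.fs_emg))
    n_kin = int(round(seconds * trial.fs_kin))
    n_cop = int(round(seconds * trial.fs_cop))
    return TrialRecording(
        emg=trial.emg[:, n_emg:],
        fs_emg=trial.fs_emg,
        markers={k: v[n_kin:] for k, v in trial.markers.items()},
        fs_kin=trial.fs_kin,
        cop=trial.cop[n_cop:],
        fs_cop=trial.fs_cop,
        beam=trial.beam,
        meta=trial.meta,
    )


def detect_heelstrikes(
    cop: np.ndarray,
    fs: float,
    min_separation: float = 0.4,
    smooth_hz: float = 10.0,
) -> np.ndarray:
    """Unlabeled heel-strike times from anterior AP-CoP extrema.

    The AP trace is zero-phase low-passed at ``smooth_hz`` (symmetric peaks
    are not biased) before peak picking with the refractory separation.
    """
    cop = np.asarray(cop, dtype=float)
    ap = cop[:, 1]
    rng_amp = np.ptp(ap)
    if rng_amp < 1e-9:
        raise ValueError("no events found: CoP is constant")
    if smooth_hz and smooth_hz < fs / 2:
        sos = sps.butter(2, smooth_hz, btype="lowpass", fs=fs, output="sos")
        ap = sps.sosfiltfilt(sos, ap)
    dist = max(int(round(min_separation * fs)), 1)
    peaks, _ = sps.find_peaks(ap, distance=dist, prominence=0.1 * rng_amp)
    if peaks.size == 0:
        raise ValueError("no events found in CoP trace")
    return peaks / fs


def assign_legs(
    event_times: np.ndarray,
    trial: TrialRecording,
    max_violation_frac: float = 0.10,
) -> GaitEvents:
    """Label each event with the foot more anterior at the event time.

    Alternation is enforced: for a run of same-leg labels, the event with
    the smaller anterior margin is dropped (logged). More than
    ``max_violation_frac`` violations raise, as this indicates detection
    failure rather than isolated label noise.
    """
    t_kin = trial.marker_time()
    ap_l = np.interp(event_times, t_kin, trial.markers["foot_l"][:, 1])
    ap_r = np.interp(event_times, t_kin, trial.markers["foot_r"][:, 1])
    legs = np.where(ap_l > ap_r, "left", "right")
    margin = np.abs(ap_l - ap_r)

    keep = np.ones(len(event_times), dtype=bool)
    n_viol = 0
    prev = None
    for i in range(len(event_times)):
        if not keep[i]:
            continue
        if prev is not None and legs[i] == legs[prev]:
            n_viol += 1
            drop = i if margin[i] <= margin[prev] else prev
            keep[drop] = False
            log.warning(
                "alternation violation at t=%.3f s: dropped event t=%.3f s",
                event_times[i], event_times[drop],
            )
            if drop == prev:
                prev = i
            continue
        prev = i
    if len(event_times) and n_viol / len(event_times) > max_violation_frac:
        raise ValueError(
            f"{n_viol}/{len(event_times)} leg-alternation violations; "
            "heel-strike detection likely failed"
        )
    times = np.asarray(event_times)[keep]
    lg = legs[keep]
    return GaitEvents(
        left=times[lg == "left"],
        right=times[lg == "right"],
        fs_kin=trial.fs_kin,
        dominant_side=trial.meta.dominant_side,
    )


def detect_events(trial: TrialRecording, min_separation: float = 0.4) -> GaitEvents:
    """Detection + leg assignment in one call."""
    times = detect_heelstrikes(trial.cop, trial.fs_cop, min_separation=min_separation)
    return assign_legs(times, trial)


def _toe_off_after(t_hs: float, t_cop: np.ndarray, ml: np.ndarray, midline: float,
                   horizon: float) -> float | None:
    """Estimated contralateral toe-off after heel-strike at ``t_hs``.

    The CoP ML transfer from the old stance foot to the new one crosses the
    midline midway through double support (symmetric feet), so toe-off is
    extrapolated as 2*t_cross - t_hs.
    """
    sel = (t_cop >= t_hs) & (t_cop <= t_hs + horizon)
    if not np.any(sel):
        return None
    tt, mm = t_cop[sel], ml[sel] - midline
    sgn = np.sign(mm)
    flips = np.nonzero(sgn[:-1] * sgn[1:] < 0)[0]
    if flips.size == 0:
        return None
    i = flips[0]
    # linear interpolation of the crossing time
    t_cross = tt[i] + (tt[i + 1] - tt[i]) * (-mm[i]) / (mm[i + 1] - mm[i])
    return 2.0 * t_cross - t_hs


def support_times(
    events: GaitEvents,
    cop: np.ndarray,
    fs_cop: float,
    n_strides: int | None = None,
) -> dict[str, float]:
    """Single- and double-support durations as percentages of stride time.

    Each dominant-leg stride decomposes as DS1 (dominant heel-strike to
    contralateral toe-off) + ipsilateral single support + DS2 (contralateral
    heel-strike to dominant toe-off) + contralateral single support; the four
    percentages sum to 100 per stride. Mean percentages over strides are
    returned.
    """
    cop = np.asarray(cop, dtype=float)
    t_cop = np.arange(cop.shape[0]) / fs_cop
    ml = cop[:, 0]
    midline = float(np.median(ml))
    strides = events.strides(n_strides)
    contra = events.nondominant
    rows = []
    for (t0, t1) in strides:
        dur = t1 - t0
        t_mid = contra[(contra >= t0) & (contra < t1)][0]
        to_contra = _toe_off_after(t0, t_cop, ml, midline, horizon=0.6 * dur)
        to_dom = _toe_off_after(t_mid, t_cop, ml, midline, horizon=0.6 * dur)
        if to_contra is None or to_dom is None:
            continue
        ds1 = to_contra - t0
        ss_dom = t_mid - to_contra
        ds2 = to_dom - t_mid
        ss_contra = t1 - to_dom
        rows.append(np.array([ds1, ss_dom, ds2, ss_contra]) / dur * 100.0)
    if not rows:
        raise ValueError("no strides with recoverable support phases")
    arr = np.mean(rows, axis=0)
    return {
        "double_support_pct": float(arr[0] + arr[2]),
        "single_support_dominant_pct": float(arr[1]),
        "single_support_nondominant_pct": float(arr[3]),
        "per_stride": np.array(rows),
    }
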