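"""EMG preprocessing: raw signal -> normalized envelopes -> stride-normalized
activation matrix E.

Filter chain (all zero-phase, forward-backward Butterworth): 50 Hz high-pass
(4th order), notch at 50 Hz and harmonics up to Nyquist (1 Hz bandwidth,
1st order), envelope as the modulus of the analytic (Hilbert) signal
low-passed at 20 Hz (2nd order). Envelopes are normalized to the per-channel
per-trial maximum, then each stride (dominant-leg heel-strike to next) is
linearly resampled onto 100 points and strides are concatenated columnwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import EMG_CHANNELS, GaitEvents


def _padlen(fs: float, char_hz: float, x: np.ndarray) -> int:
    """Forward-backward pad long enough for the filter's ~1/char_hz ring."""
    return int(min(6.0 * fs / char_hz, x.shape[-1] - 2))


def highpass(emg: np.ndarray, fs: float, cutoff: float = 50.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass, applied per channel."""
    if fs <= 2 * cutoff:
        raise ValueError(f"fs={fs} too low for a {cutoff} Hz high-pass")
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    x = np.asarray(emg, dtype=float)
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=_padlen(fs, cutoff, x))


def notch_harmonics(
    emg: np.ndarray, fs: float, base: float = 50.0, bw: float = 1.0, order: int = 1
) -> np.ndarray:
    """Cascaded zero-phase band-stops at base, 2*base, ... below Nyquist."""
    if base >= fs / 2:
        raise ValueError("notch base frequency must be below Nyquist")
    out = np.asarray(emg, dtype=float)
    pad = _padlen(fs, bw, out)  # narrow stops ring for ~1/bw seconds
    f = base
    while f < fs / 2:
        lo, hi = f - bw / 2.0, min(f + bw / 2.0, fs / 2 * 0.999)
        sos = signal.butter(order, [lo, hi], btype="bandstop", fs=fs, output="sos")
        out = signal.sosfiltfilt(sos, out, axis=-1, padlen=pad)
        f += base
    return out


def envelope(emg: np.ndarray, fs: float, lp: float = 20.0, order: int = 2) -> np.ndarray:
    """Rectified analytic-signal magnitude, zero-phase low-passed.

    The modulus of the Hilbert analytic signal is nonnegative by
    construction; the low-pass smooths it into an activation envelope.
    Filter ringing may produce tiny negative excursions, which are clipped.
    """
    analytic = signal.hilbert(np.asarray(emg, dtype=float), axis=-1)
    rect = np.abs(analytic)
    sos = signal.butter(order, lp, btype="lowpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rect, axis=-1, padlen=_padlen(fs, lp, rect))
    return np.clip(filtered, 0.0, None)


def normalize(env: np.ndarray, channels: tuple[str, ...] = EMG_CHANNELS) -> np.ndarray:
    """Scale each channel by its own per-trial maximum (max becomes 1)."""
    env = np.asarray(env, dtype=float)
    mx = env.max(axis=-1, keepdims=True)
    dead = np.nonzero(mx.ravel() <= 0)[0]
    if dead.size:
        names = [channels[i] if i < len(channels) else str(i) for i in dead]
        raise ValueError(f"all-zero channel(s): {', '.join(names)}")
    return env / mx


@dataclass
class StrideNormalizedEMG:
    """E matrix: muscles x (strides * samples), values in [0, 1]."""

    E: np.ndarray
    n_strides: int
    samples_per_stride: int
    muscles: tuple[str, ...] = EMG_CHANNELS
    stride_intervals: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.E.shape != (len(self.muscles), self.n_strides * self.samples_per_stride):
            raise ValueError(
                f"E shape {self.E.shape} inconsistent with "
                f"{len(self.muscles)} x {self.n_strides}*{self.samples_per_stride}"
            )

    def stride_view(self) -> np.ndarray:
        """(muscles, strides, samples) view of E."""
        return self.E.reshape(len(self.muscles), self.n_strides, self.samples_per_stride)


def time_normalize(
    env: np.ndarray,
    fs: float,
    events: GaitEvents,
    samples: int = 100,
    n_strides: int = 160,
) -> StrideNormalizedEMG:
    """Resample each dominant-leg stride onto ``samples`` points.

    The stride interval is half-open: the grid runs from the heel-strike up
    to (but excluding) the next heel-strike. The first ``n_strides`` complete
    strides are kept and concatenated columnwise into E.
    """
    env = np.atleast_2d(np.asarray(env, dtype=float))
    strides = events.strides(n_strides)  # raises if insufficient
    t = np.arange(env.shape[1]) / fs
    cols = []
    for (t0, t1) in strides:
        if t1 <= t0:
            raise ValueError("stride boundaries misordered")
        grid = t0 + (t1 - t0) * np.arange(samples) / samples
        cols.append(np.stack([np.interp(grid, t, ch) for ch in env], axis=0))
    E = np.concatenate(cols, axis=1)
    muscles = EMG_CHANNELS if env.shape[0] == len(EMG_CHANNELS) else tuple(
        f"ch{i}" for i in range(env.shape[0]))
    return StrideNormalizedEMG(
        E=E, n_strides=len(strides), samples_per_stride=samples,
        muscles=muscles, stride_intervals=tuple(strides),
    )


def preprocess(
    emg: np.ndarray,
    fs: float,
    events: GaitEvents,
    hp_cutoff: float = 50.0,
    notch_base: float = 50.0,
    notch_bw: float = 1.0,
    lp_cutoff: float = 20.0,
    samples_per_stride: int = 100,
    n_strides: int = 160,
) -> StrideNormalizedEMG:
    """Full chain: high-pass -> notch harmonics -> envelope -> per-trial
    max normalization -> stride-time normalization."""
    x = highpass(emg, fs, cutoff=hp_cutoff)
    x = notch_harmonics(x, fs, base=notch_base, bw=notch_bw)
    env = normalize(envelope(x, fs, lp=lp_cutoff))
    return time_normalize(env, fs, events, samples=samples_per_stride,
                          n_strides=n_strides)
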