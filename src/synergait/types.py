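"""Core containers shared across the pipeline.

Coordinate convention: mediolateral (ML) = x, anterior-posterior (AP) = y,
vertical = z, units meters, treadmill frame fixed, right-handed. Time is in
seconds from trial start; intervals are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The 11 surface-EMG channels: 5 unilateral muscles of the dominant leg
#: (tibialis anterior, vastus lateralis, lateral gastrocnemius, soleus,
#: peroneus longus) and 3 bilateral muscles (rectus femoris, biceps femoris,
#: gluteus medius; D = dominant, N = non-dominant side).
EMG_CHANNELS: tuple[str, ...] = (
    "TAD", "VLD", "GLD", "SOD", "PLD",
    "RFD", "RFN", "BFD", "BFN", "GMD", "GMN",
)

TIME_POINTS: tuple[str, ...] = ("Pre", "Post1", "Post2")
CONDITIONS: tuple[str, ...] = ("normal", "narrow")

#: Marker names required in every trial. "trunk" is the trunk-cluster
#: centroid; foot_* are the per-foot reference points (mid-calcaneus);
#: *_med / *_lat are the medial/lateral foot edges used for beam scoring.
MARKER_NAMES: tuple[str, ...] = (
    "trunk",
    "foot_l", "foot_r",
    "foot_l_med", "foot_l_lat",
    "foot_r_med", "foot_r_lat",
)


@dataclass(frozen=True)
class BeamGeometry:
    """Projected light-beam path on the treadmill (narrow-base condition)."""

    center_ml: float = 0.0
    width: float = 0.12  # 12 cm beam

    @property
    def halfwidth(self) -> float:
        return self.width / 2.0

    @property
    def edges(self) -> tuple[float, float]:
        return (self.center_ml - self.halfwidth, self.center_ml + self.halfwidth)


@dataclass(frozen=True)
class TrialMeta:
    subject: str
    time_point: str = "Pre"
    condition: str = "normal"
    dominant_side: str = "right"

    def __post_init__(self) -> None:
        if self.time_point not in TIME_POINTS:
            raise ValueError(f"unknown time_point {self.time_point!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.dominant_side not in ("left", "right"):
            raise ValueError(f"dominant_side must be 'left' or 'right'")


@dataclass
class TrialRecording:
    """One subject x condition x time-point treadmill recording.

    emg      : (11, T_emg) volts at ``fs_emg`` (2000 Hz nominal)
    markers  : name -> (T_kin, 3) meters at ``fs_kin`` (50 Hz nominal)
    cop      : (T_cop, 2) center of pressure, columns (ML, AP), meters
    beam     : beam geometry for narrow-base trials, else None
    """

    emg: np.ndarray
    fs_emg: float
    markers: dict[str, np.ndarray]
    fs_kin: float
    cop: np.ndarray
    fs_cop: float
    beam: Optional[BeamGeometry]
    meta: TrialMeta
    channels: tuple[str, ...] = EMG_CHANNELS

    def __post_init__(self) -> None:
        self.validate()

    @property
    def duration(self) -> float:
        return self.markers["trunk"].shape[0] / self.fs_kin

    def validate(self) -> None:
        if tuple(self.channels) != EMG_CHANNELS:
            raise ValueError(
                f"EMG channels must be exactly {list(EMG_CHANNELS)}, "
                f"got {list(self.channels)}"
            )
        if self.emg.shape[0] != len(EMG_CHANNELS):
            raise ValueError(f"emg must have {len(EMG_CHANNELS)} rows")
        for name in MARKER_NAMES:
            if name not in self.markers:
                raise ValueError(f"missing marker {name!r}")
        if self.cop.ndim != 2 or self.cop.shape[1] != 2:
            raise ValueError("cop must be (T, 2) with columns (ML, AP)")
        # all streams share a start time; durations within one kinematic
        # sample of each other after rate conversion
        durs = [
            self.emg.shape[1] / self.fs_emg,
            self.markers["trunk"].shape[0] / self.fs_kin,
            self.cop.shape[0] / self.fs_cop,
        ]
        if max(durs) - min(durs) > 1.0 / self.fs_kin + 1e-9:
            raise ValueError(
                f"stream durations disagree by more than one kinematic "
                f"sample: {durs}"
            )
        if self.meta.condition == "narrow" and self.beam is None:
            raise ValueError("narrow-base trial requires beam geometry")

    def marker_time(self) -> np.ndarray:
        n = self.markers["trunk"].shape[0]
        return np.arange(n) / self.fs_kin

    def cop_time(self) -> np.ndarray:
        return np.arange(self.cop.shape[0]) / self.fs_cop

    def emg_time(self) -> np.ndarray:
        return np.arange(self.emg.shape[1]) / self.fs_emg


@dataclass
class GaitEvents:
    """Labeled heel-strike times and dominant-leg stride intervals."""

    left: np.ndarray   # heel-strike times (s), left leg
    right: np.ndarray  # heel-strike times (s), right leg
    fs_kin: float
    dominant_side: str = "right"

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        for leg, t in (("left", self.left), ("right", self.right)):
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{leg} heel-strike times not strictly increasing")
        lab = self.labeled()
        legs = [l for _, l in lab]
        for a, b in zip(legs, legs[1:]):
            if a == b:
                raise ValueError("heel-strikes do not alternate between legs")

    def labeled(self) -> list[tuple[float, str]]:
        """All events as (time, leg), time-sorted."""
        ev = [(t, "left") for t in self.left] + [(t, "right") for t in self.right]
        ev.sort()
        return ev

    @property
    def dominant(self) -> np.ndarray:
        return self.right if self.dominant_side == "right" else self.left

    @property
    def nondominant(self) -> np.ndarray:
        return self.left if self.dominant_side == "right" else self.right

    def strides(self, n: Optional[int] = None) -> list[tuple[float, float]]:
        """Dominant heel-strike to next dominant heel-strike, half-open.

        Only strides containing exactly one contralateral heel-strike are
        returned (a missed contralateral event invalidates the stride).
        """
        dom = self.dominant
        contra = self.nondominant
        out = []
        for t0, t1 in zip(dom[:-1], dom[1:]):
            inside = np.sum((contra >= t0) & (contra < t1))
            if inside == 1:
                out.append((float(t0), float(t1)))
        if n is not None:
            if len(out) < n:
                raise ValueError(
                    f"insufficient strides: need {n}, have {len(out)}"
                )
            out = out[:n]
        return out

    def n_strides(self) -> int:
        return len(self.strides())
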