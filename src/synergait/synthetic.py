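"""Synthetic treadmill-walking cohorts with known ground truth.

Every downstream stage (EMG preprocessing, event detection, gait metrics,
local divergence exponents, synergy extraction, statistics) is exercised
against trials produced here. The generator emulates the study conditions:
11-channel surface EMG at 2000 Hz built from known synergy weightings and
Gaussian activation bumps amplitude-modulating band-limited carrier noise,
50 Hz marker kinematics with stride-to-stride variability and a tunable
divergence gain, and a center-of-pressure "butterfly" trace whose anterior
extrema fall at known heel-strike times.

All quantities are reproducible bit-exact given (seed, parameters); the
stored ground truth is sufficient to score every downstream estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .types import (
    CONDITIONS,
    EMG_CHANNELS,
    TIME_POINTS,
    BeamGeometry,
    TrialMeta,
    TrialRecording,
)

TREADMILL_SPEED_KMH = 3.5
#: nominal stride time at 3.5 km/h (~1.0-1.2 s band)
DEFAULT_STRIDE_S = 1.08
DEFAULT_STRIDE_CV = 0.03  # log-normal stride-duration jitter


@dataclass(frozen=True)
class SynergyProfile:
    """Gaussian activation bump in gait-cycle coordinates.

    center and width (sigma) are in % of the gait cycle (dominant-leg
    heel-strike = 0%); amplitude is unitless.
    """

    center: float
    width: float
    amplitude: float = 1.0


# Five synergies mirroring the roles reported for treadmill walking:
# 1 dominant-leg stance/push-off (soleus, lateral gastrocnemius, peroneus),
# 2 dominant-leg weight acceptance (vastus lateralis, rectus femoris),
# 3 non-dominant stance (gluteus medius, rectus femoris non-dominant),
# 4 pre dominant heel-strike (biceps femoris dominant, tibialis anterior),
# 5 pre non-dominant heel-strike (biceps femoris non-dominant).
DEFAULT_PROFILES: tuple[SynergyProfile, ...] = (
    SynergyProfile(center=30.0, width=6.0, amplitude=1.0),
    SynergyProfile(center=10.0, width=4.5, amplitude=1.2),
    SynergyProfile(center=65.0, width=6.0, amplitude=1.1),
    SynergyProfile(center=90.0, width=4.5, amplitude=1.5),
    SynergyProfile(center=48.0, width=4.5, amplitude=1.7),
)

# columns: synergies 1..5, rows: EMG_CHANNELS order
DEFAULT_W = np.array(
    [  # s1    s2    s3    s4    s5
        [0.10, 0.15, 0.02, 0.50, 0.02],  # TAD
        [0.02, 1.00, 0.02, 0.02, 0.02],  # VLD
        [0.90, 0.02, 0.02, 0.02, 0.02],  # GLD
        [1.00, 0.10, 0.02, 0.02, 0.02],  # SOD
        [0.45, 0.15, 0.02, 0.10, 0.02],  # PLD
        [0.02, 0.90, 0.10, 0.02, 0.02],  # RFD
        [0.02, 0.02, 0.80, 0.02, 0.15],  # RFN
        [0.05, 0.02, 0.02, 1.00, 0.10],  # BFD
        [0.02, 0.02, 0.10, 0.10, 1.00],  # BFN
        [0.15, 0.30, 0.40, 0.02, 0.02],  # GMD
        [0.02, 0.02, 1.00, 0.02, 0.10],  # GMN
    ]
)


def _max_normalize_columns(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("synergy weightings must be nonnegative")
    return W / W.max(axis=0, keepdims=True)


@dataclass
class GroundTruth:
    """Everything needed to score downstream estimates of one trial."""

    W_true: np.ndarray                     # (11, k), columns max-normalized
    profiles: tuple[SynergyProfile, ...]   # per-synergy bump parameters
    right_hs: np.ndarray                   # heel-strike times (s), right leg
    left_hs: np.ndarray
    foot_centers: dict[str, np.ndarray]    # per-leg ML placement per heel-strike (m)
    ds_frac: float = 0.10                  # double-support fraction of stride, per side
    foot_width: float = 0.10               # m, edge-to-edge
    beam_halfwidth: float = 0.06           # m; 12 cm projected beam
    divergence_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.W_true = _max_normalize_columns(self.W_true)
        if self.W_true.shape != (len(EMG_CHANNELS), len(self.profiles)):
            raise ValueError(
                f"W_true shape {self.W_true.shape} does not match "
                f"{len(EMG_CHANNELS)} muscles x {len(self.profiles)} synergies"
            )
        for leg in ("left", "right"):
            t = getattr(self, f"{leg}_hs")
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"{leg} event times not strictly increasing")
        merged = np.sort(np.concatenate([self.left_hs, self.right_hs]))
        right_set = set(self.right_hs)
        legs = ["right" if t in right_set else "left" for t in merged]
        for a, b in zip(legs, legs[1:]):
            if a == b:
                raise ValueError("left/right heel-strikes must alternate")

    @property
    def k(self) -> int:
        return len(self.profiles)

    @property
    def duration(self) -> float:
        return float(self.right_hs[-1])

    @property
    def n_strides(self) -> int:
        return len(self.right_hs) - 1

    def stride_phase(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional dominant-leg (right) stride index at times t.

        Returns (stride index, phase in [0,1))."""
        u = np.interp(t, self.right_hs, np.arange(len(self.right_hs)))
        idx = np.minimum(np.floor(u).astype(int), self.n_strides - 1)
        return idx, u - np.floor(u)

    def true_profile(self, phase_pct: np.ndarray, s: int) -> np.ndarray:
        """Noise-free activation of synergy ``s`` at phase (% cycle)."""
        p = self.profiles[s]
        d = (phase_pct - p.center + 50.0) % 100.0 - 50.0
        return p.amplitude * np.exp(-0.5 * (d / p.width) ** 2)

    def events_for(self, leg: str) -> np.ndarray:
        return self.right_hs if leg == "right" else self.left_hs


def make_ground_truth(
    n_strides: int = 160,
    lead_in: float = 35.0,
    stride_mean: float = DEFAULT_STRIDE_S,
    stride_cv: float = DEFAULT_STRIDE_CV,
    step_width_mean: float = 0.12,
    step_width_sd: float = 0.01,
    ds_frac: float = 0.10,
    divergence_gain: float = 0.0,
    profiles: Optional[Sequence[SynergyProfile]] = None,
    W: Optional[np.ndarray] = None,
    foot_width: float = 0.10,
    beam_halfwidth: float = 0.06,
    seed: int = 0,
) -> GroundTruth:
    """Draw stride timing and foot placements for one trial.

    ``lead_in`` extra seconds of walking are prepended so that ``n_strides``
    complete strides survive the pipeline's initial trim; the analysis
    stages, not the generator, perform that trim.
    """
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")
    if step_width_sd < 0:
        raise ValueError("step_width_sd must be >= 0")
    profiles = tuple(profiles) if profiles is not None else DEFAULT_PROFILES
    W = np.array(W, dtype=float) if W is not None else DEFAULT_W.copy()
    if W.shape[1] != len(profiles):
        raise ValueError(
            f"W has {W.shape[1]} columns but {len(profiles)} synergy "
            f"profiles were given"
        )
    rng = np.random.default_rng([seed, 0xA11CE])

    n_total = n_strides + math.ceil(lead_in / (stride_mean * 0.9)) + 2
    if stride_cv > 0:
        sig = math.sqrt(math.log(1.0 + stride_cv**2))
        mu = math.log(stride_mean) - 0.5 * sig**2
        durations = rng.lognormal(mu, sig, size=n_total)
    else:
        durations = np.full(n_total, stride_mean)
    right_hs = np.concatenate([[0.0], np.cumsum(durations)])
    left_hs = right_hs[:-1] + 0.5 * durations  # contralateral at 50% cycle

    half = step_width_mean / 2.0
    jitter = step_width_sd / math.sqrt(2.0)
    foot_centers = {
        "right": half + jitter * rng.standard_normal(len(right_hs)),
        "left": -half + jitter * rng.standard_normal(len(left_hs)),
    }
    return GroundTruth(
        W_true=W,
        profiles=profiles,
        right_hs=right_hs,
        left_hs=left_hs,
        foot_centers=foot_centers,
        ds_frac=ds_frac,
        foot_width=foot_width,
        beam_halfwidth=beam_halfwidth,
        divergence_gain=divergence_gain,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# EMG synthesis
# ---------------------------------------------------------------------------

@dataclass
class EMGSynthesis:
    emg: np.ndarray            # (11, T) raw signal
    fs: float
    true_envelope: np.ndarray  # (11, T) noise-free modulator
    true_activations: np.ndarray  # (k, T)


def gen_emg(
    gt: GroundTruth,
    fs: float = 2000.0,
    snr_db: float = 20.0,
    line_hz: Optional[float] = None,
    baseline: float = 0.02,
    amp_jitter: float = 0.05,
    center_jitter: float = 1.0,
    residual_level: float = 1.0,
) -> EMGSynthesis:
    """Synthesize raw surface EMG from the stored synergies.

    Each channel is sum_s W_true[m, s] * A_s(t) amplitude-modulating a
    zero-mean 20-450 Hz band-limited Gaussian carrier, plus white noise at
    ``snr_db`` and an optional line-interference sinusoid at ``line_hz``.
    Per-stride bump amplitude/center jitter provides stride-to-stride
    variability; the realized (jittered) envelope is stored as ground truth.
    """
    rng = np.random.default_rng([gt.seed, 0xE316])
    k = gt.k
    t = np.arange(0.0, gt.duration, 1.0 / fs)
    idx, phase = gt.stride_phase(t)
    pct = phase * 100.0

    n_str = gt.n_strides
    A = np.empty((k, t.size))
    for s, prof in enumerate(gt.profiles):
        amps = prof.amplitude * np.clip(
            1.0 + amp_jitter * rng.standard_normal(n_str), 0.1, None)
        centers = prof.center + center_jitter * rng.standard_normal(n_str)
        d = (pct - centers[idx] + 50.0) % 100.0 - 50.0
        A[s] = amps[idx] * np.exp(-0.5 * (d / prof.width) ** 2)

    env = gt.W_true @ A + baseline
    if residual_level > 0:
        # per-muscle residual activity outside the synergy model: smooth
        # positive fluctuations, sized relative to each muscle's synergy
        # drive, so the low-rank factorization leaves realistic unexplained
        # variance (a handful of synergies accounts for ~85-90%, not ~99%)
        sos_r = signal.butter(2, 15.0, btype="lowpass", fs=fs, output="sos")
        z = signal.sosfiltfilt(sos_r, rng.standard_normal(env.shape), axis=1)
        z = np.clip(z, 0.0, None)  # sporadic bursts, mostly silent
        z /= np.sqrt(np.mean(z**2, axis=1, keepdims=True))
        env = env + residual_level * np.sqrt(
            np.mean(env**2, axis=1, keepdims=True)) * z

    # band-limited carrier, unit RMS per channel
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfiltfilt(sos, rng.standard_normal(env.shape), axis=1)
    carrier /= np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))

    emg = env * carrier
    if np.isfinite(snr_db):
        sig_rms = np.sqrt(np.mean(emg**2, axis=1, keepdims=True))
        emg = emg + sig_rms * 10.0 ** (-snr_db / 20.0) * rng.standard_normal(emg.shape)
    if line_hz is not None:
        amp = 0.2 * float(np.mean(np.sqrt(np.mean(emg**2, axis=1))))
        phases = rng.uniform(0, 2 * np.pi, size=emg.shape[0])
        emg = emg + amp * np.sin(2 * np.pi * line_hz * t + phases[:, None])
    return EMGSynthesis(emg=emg, fs=fs, true_envelope=env, true_activations=A)


# ---------------------------------------------------------------------------
# Kinematics + CoP synthesis
# ---------------------------------------------------------------------------

@dataclass
class KinematicsSynthesis:
    markers: dict[str, np.ndarray]  # name -> (T, 3)
    fs: float
    cop: np.ndarray                 # (T, 2) columns (ML, AP)
    fs_cop: float


def _ar1(rng: np.random.Generator, n: int, fs: float, tau: float = 0.5) -> np.ndarray:
    """Unit-variance Ornstein-Uhlenbeck-style smooth noise."""
    pole = math.exp(-1.0 / (tau * fs))
    innov = math.sqrt(1.0 - pole**2)
    x = np.empty(n)
    acc = rng.standard_normal() if n else 0.0
    eps = rng.standard_normal(n)
    for i in range(n):
        acc = pole * acc + innov * eps[i]
        x[i] = acc
    return x


def _leg_phase(t: np.ndarray, hs: np.ndarray) -> np.ndarray:
    u = np.interp(t, hs, np.arange(len(hs)))
    return u - np.floor(u)


def _foot_ml_track(
    t: np.ndarray, hs: np.ndarray, centers: np.ndarray, stance_frac: float = 0.6
) -> np.ndarray:
    """Piecewise track: constant at the placement during stance, cosine
    blend to the next placement during swing."""
    u = np.interp(t, hs, np.arange(len(hs)))
    i = np.minimum(np.floor(u).astype(int), len(hs) - 2)
    frac = np.clip(u - i, 0.0, 1.0)
    blend = np.where(
        frac < stance_frac,
        0.0,
        0.5 * (1.0 - np.cos(np.pi * (frac - stance_frac) / (1.0 - stance_frac))),
    )
    return centers[i] * (1.0 - blend) + centers[i + 1] * blend


def gen_kinematics(
    gt: GroundTruth,
    fs: float = 50.0,
    cop_noise_rms: float = 0.0,
    marker_noise_rms: float = 1e-4,
    trunk_amp: float = 0.025,
    cop_ap_amp: float = 0.08,
    foot_ap_amp: float = 0.35,
) -> KinematicsSynthesis:
    """Marker trajectories and CoP butterfly consistent with the stored events.

    The trunk ML trajectory is a stochastic limit cycle: a harmonic base that
    is a pure function of gait phase, with amplitude and phase perturbed by
    smooth noise scaled by ``divergence_gain`` (gain 0 -> trajectory is
    exactly periodic in gait-phase coordinates). The CoP anterior-posterior
    component peaks at every heel-strike; the ML component transfers linearly
    between stance feet over the double-support interval.
    """
    if gt.n_strides < 1:
        raise ValueError("ground truth must contain at least one stride")
    rng = np.random.default_rng([gt.seed, 0x514])
    t = np.arange(0.0, gt.duration, 1.0 / fs)
    _, phase = gt.stride_phase(t)
    g = gt.divergence_gain

    amp_noise = _ar1(rng, t.size, fs, tau=2.0) if g > 0 else np.zeros(t.size)
    ph_noise = _ar1(rng, t.size, fs, tau=2.0) if g > 0 else np.zeros(t.size)
    trunk_ml = (
        trunk_amp * (1.0 + 0.3 * g * amp_noise)
        * np.sin(2 * np.pi * (phase + 0.04 * g * ph_noise))
        + 0.3 * trunk_amp * np.sin(4 * np.pi * phase + 0.8)
    )
    trunk = np.column_stack([
        trunk_ml,
        0.01 * np.sin(4 * np.pi * phase),
        1.0 + 0.01 * np.cos(4 * np.pi * phase),
    ])

    markers: dict[str, np.ndarray] = {"trunk": trunk}
    for leg in ("left", "right"):
        hs = gt.events_for(leg)
        ml = _foot_ml_track(t, hs, gt.foot_centers[leg])
        psi = _leg_phase(t, hs)
        ap = foot_ap_amp * np.cos(2 * np.pi * psi)
        z = 0.02 * 0.5 * (1.0 - np.cos(2 * np.pi * psi))
        ref = np.column_stack([ml, ap, z])
        markers[f"foot_{leg[0]}"] = ref
        half_w = gt.foot_width / 2.0
        medial_sign = +1.0 if leg == "left" else -1.0  # medial = toward midline
        markers[f"foot_{leg[0]}_med"] = ref + np.array([medial_sign * half_w, 0, 0])
        markers[f"foot_{leg[0]}_lat"] = ref + np.array([-medial_sign * half_w, 0, 0])

    # --- CoP ---
    events = gt.right_hs.tolist() + gt.left_hs.tolist()
    legs = ["right"] * len(gt.right_hs) + ["left"] * len(gt.left_hs)
    order = np.argsort(events)
    ev_t = np.asarray(events)[order]
    ev_leg = [legs[i] for i in order]
    ev_ml = np.array([
        gt.foot_centers[leg][np.searchsorted(gt.events_for(leg), tt)]
        if np.searchsorted(gt.events_for(leg), tt) < len(gt.foot_centers[leg])
        else gt.foot_centers[leg][-1]
        for tt, leg in zip(ev_t, ev_leg)
    ])
    # exact index lookup (searchsorted on the striking foot's own HS list)
    for j, (tt, leg) in enumerate(zip(ev_t, ev_leg)):
        i = int(np.searchsorted(gt.events_for(leg), tt))
        i = min(i, len(gt.foot_centers[leg]) - 1)
        ev_ml[j] = gt.foot_centers[leg][i]

    step_u = np.interp(t, ev_t, np.arange(ev_t.size))
    cop_ap = cop_ap_amp * np.cos(2 * np.pi * (step_u - np.floor(step_u)))

    cop_ml = np.empty(t.size)
    j_idx = np.minimum(np.floor(step_u).astype(int), ev_t.size - 2)
    for j in range(ev_t.size - 1):
        sel = j_idx == j
        if not np.any(sel):
            continue
        step_dur = ev_t[j + 1] - ev_t[j]
        ds = 2.0 * gt.ds_frac * step_dur  # ds_frac is per stride; step ~ stride/2
        prev_ml = ev_ml[j - 1] if j > 0 else ev_ml[j]
        frac = np.clip((t[sel] - ev_t[j]) / max(ds, 1e-9), 0.0, 1.0)
        cop_ml[sel] = prev_ml + frac * (ev_ml[j] - prev_ml)
    cop = np.column_stack([cop_ml, cop_ap])
    if cop_noise_rms > 0:
        cop = cop + cop_noise_rms * rng.standard_normal(cop.shape)
    if marker_noise_rms > 0:  # optical-capture sensor noise (~0.1 mm RMS)
        for name in markers:
            markers[name] = markers[name] + marker_noise_rms * rng.standard_normal(
                markers[name].shape)
    return KinematicsSynthesis(markers=markers, fs=fs, cop=cop, fs_cop=fs)


# ---------------------------------------------------------------------------
# Whole trials and cohorts
# ---------------------------------------------------------------------------

def gen_trial(
    gt: GroundTruth,
    meta: TrialMeta,
    include_emg: bool = True,
    snr_db: float = 20.0,
    line_hz: Optional[float] = None,
    fs_emg: float = 2000.0,
    fs_kin: float = 50.0,
    cop_noise_rms: float = 0.0,
) -> TrialRecording:
    """Assemble a TrialRecording (EMG + kinematics + CoP) from ground truth."""
    kin = gen_kinematics(gt, fs=fs_kin, cop_noise_rms=cop_noise_rms)
    if include_emg:
        emg = gen_emg(gt, fs=fs_emg, snr_db=snr_db, line_hz=line_hz)
        emg_arr, fs_e = emg.emg, emg.fs
    else:
        n = int(round(kin.markers["trunk"].shape[0] / fs_kin * fs_emg))
        emg_arr, fs_e = np.zeros((len(EMG_CHANNELS), n)) + 1e-6, fs_emg
    beam = BeamGeometry(0.0, 2 * gt.beam_halfwidth) if meta.condition == "narrow" else None
    return TrialRecording(
        emg=emg_arr, fs_emg=fs_e,
        markers=kin.markers, fs_kin=kin.fs,
        cop=kin.cop, fs_cop=kin.fs_cop,
        beam=beam, meta=meta,
    )


@dataclass
class CohortEffects:
    """Imposed condition/time-point offsets, recorded as ground truth.

    Keys of each dict are (time_point, condition) pairs; missing keys mean
    "no imposed effect". ``bump_width_scale`` / ``bump_center_shift`` map a
    synergy index to a multiplicative width factor / additive center shift
    (% cycle).
    """

    step_width_mean: dict[tuple[str, str], float] = field(default_factory=dict)
    bump_width_scale: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    bump_center_shift: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    divergence_gain: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def null(cls) -> "CohortEffects":
        return cls()


@dataclass
class CohortTrialSpec:
    """Lazily materialized trial: ground truth is built on first access."""

    meta: TrialMeta
    gt_kwargs: dict
    include_emg: bool
    snr_db: float
    cop_noise_rms: float
    _gt: Optional[GroundTruth] = None

    def ground_truth(self) -> GroundTruth:
        if self._gt is None:
            self._gt = make_ground_truth(**self.gt_kwargs)
        return self._gt

    def make(self) -> TrialRecording:
        return gen_trial(
            self.ground_truth(), self.meta,
            include_emg=self.include_emg, snr_db=self.snr_db,
            cop_noise_rms=self.cop_noise_rms,
        )


@dataclass
class Cohort:
    trials: list[CohortTrialSpec]
    effects: CohortEffects
    seed: int

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for tr in self.trials:
            if tr.meta.subject not in seen:
                seen.append(tr.meta.subject)
        return seen


def gen_cohort(
    n_subjects: int,
    effects: Optional[CohortEffects] = None,
    seed: int = 0,
    n_strides: int = 160,
    lead_in: float = 35.0,
    include_emg: bool = True,
    snr_db: float = 20.0,
    cop_noise_rms: float = 0.0,
    base_step_width: Optional[dict[str, float]] = None,
    step_width_sd: float = 0.01,
    subject_step_width_sd: float = 0.008,
    subject_center_sd: float = 1.5,
    base_divergence_gain: float = 0.3,
) -> Cohort:
    """3 time-points x 2 conditions per subject, with imposed effects.

    Between-subject variability (step-width offsets, bump-center offsets)
    makes repeated-measures structure real; imposed effects from ``effects``
    are additive/multiplicative on top and recorded for recovery tests.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    effects = effects if effects is not None else CohortEffects.null()
    base_step_width = base_step_width or {"normal": 0.12, "narrow": 0.05}
    rng = np.random.default_rng([seed, 0xC0C0])
    trials: list[CohortTrialSpec] = []
    for si in range(n_subjects):
        subj = f"S{si + 1:02d}"
        sw_off = subject_step_width_sd * rng.standard_normal()
        c_off = subject_center_sd * rng.standard_normal(len(DEFAULT_PROFILES))
        for tp in TIME_POINTS:
            for cond in CONDITIONS:
                key = (tp, cond)
                sw = base_step_width[cond] + sw_off + effects.step_width_mean.get(key, 0.0)
                profiles = []
                for s, p in enumerate(DEFAULT_PROFILES):
                    w = p.width * effects.bump_width_scale.get(key, {}).get(s, 1.0)
                    c = (p.center + c_off[s]
                         + effects.bump_center_shift.get(key, {}).get(s, 0.0)) % 100.0
                    profiles.append(SynergyProfile(center=c, width=w,
                                                  amplitude=p.amplitude))
                gain = base_divergence_gain + effects.divergence_gain.get(key, 0.0)
                trial_seed = int(rng.integers(0, 2**31 - 1))
                trials.append(CohortTrialSpec(
                    meta=TrialMeta(subject=subj, time_point=tp, condition=cond),
                    gt_kwargs=dict(
                        n_strides=n_strides, lead_in=lead_in,
                        step_width_mean=max(sw, 0.01),
                        step_width_sd=step_width_sd,
                        divergence_gain=gain,
                        profiles=tuple(profiles),
                        seed=trial_seed,
                    ),
                    include_emg=include_emg, snr_db=snr_db,
                    cop_noise_rms=cop_noise_rms,
                ))
    return Cohort(trials=trials, effects=effects, seed=seed)
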