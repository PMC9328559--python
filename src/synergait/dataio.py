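"""On-disk layout: per-trial CSV files with a JSON metadata sidecar.

A trial directory contains ``emg.csv`` (one column per channel),
``markers.csv`` (``<name>_x/_y/_z`` columns), ``cop.csv`` (``ml``, ``ap``)
and ``meta.json`` (sampling rates, units, axis convention, subject /
time-point / condition, beam geometry). A cohort is a ``manifest.json``
listing trial directories; synthetic ground truth goes in a
``ground_truth.json`` sidecar. Results are tidy long-format CSV tables with
a deterministic column order. All writers/readers round-trip exactly
(floats serialized via repr).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import Cohort, GroundTruth, SynergyProfile
from .types import EMG_CHANNELS, MARKER_NAMES, BeamGeometry, TrialMeta, TrialRecording

log = logging.getLogger(__name__)

AXIS_CONVENTION = "ML=x, AP=y, vertical=z, meters, right-handed"
MAX_GAP_S = 0.2
MAX_NAN_FRAC = 0.05

RESULT_COLUMNS = ["subject", "time_point", "condition", "metric", "value"]


def write_trial(trial: TrialRecording, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(trial.emg.T, columns=list(trial.channels)).to_csv(
        out / "emg.csv", index=False, float_format="%.17g")
    mcols = {}
    for name in MARKER_NAMES:
        for ax, j in zip("xyz", range(3)):
            mcols[f"{name}_{ax}"] = trial.markers[name][:, j]
    pd.DataFrame(mcols).to_csv(out / "markers.csv", index=False, float_format="%.17g")
    pd.DataFrame(trial.cop, columns=["ml", "ap"]).to_csv(out / "cop.csv", index=False, float_format="%.17g")
    meta = {
        "subject": trial.meta.subject,
        "time_point": trial.meta.time_point,
        "condition": trial.meta.condition,
        "dominant_side": trial.meta.dominant_side,
        "fs_emg": trial.fs_emg,
        "fs_kin": trial.fs_kin,
        "fs_cop": trial.fs_cop,
        "units": "V (EMG), m (kinematics)",
        "axis_convention": AXIS_CONVENTION,
        "beam": None if trial.beam is None else {
            "center_ml": trial.beam.center_ml, "width": trial.beam.width},
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def _fill_gaps(x: np.ndarray, fs: float, name: str) -> np.ndarray:
    """Linearly interpolate NaN runs up to MAX_GAP_S; longer runs raise."""
    x = np.array(x, dtype=float)
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    # locate runs; a single long dropout is reported as a gap error before
    # the overall NaN budget is considered
    edges = np.diff(np.concatenate([[0], bad.view(np.int8), [0]]))
    starts, ends = np.nonzero(edges == 1)[0], np.nonzero(edges == -1)[0]
    max_run = int(round(MAX_GAP_S * fs))
    for s, e in zip(starts, ends):
        if e - s > max_run:
            raise ValueError(
                f"{name}: marker gap of {(e - s) / fs:.2f} s exceeds "
                f"{MAX_GAP_S} s")
    if bad.mean() > MAX_NAN_FRAC:
        raise ValueError(f"{name}: NaN fraction {bad.mean():.1%} exceeds "
                         f"{MAX_NAN_FRAC:.0%}")
    idx = np.arange(x.size)
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    log.info("%s: filled %d gap(s) totalling %d samples", name, len(starts),
             int(bad.sum()))
    return x


def read_trial(trial_dir: str | Path) -> TrialRecording:
    d = Path(trial_dir)
    meta = json.loads((d / "meta.json").read_text())
    emg_df = pd.read_csv(d / "emg.csv", float_precision="round_trip")
    if list(emg_df.columns) != list(EMG_CHANNELS):
        missing = set(EMG_CHANNELS) - set(emg_df.columns)
        extra = set(emg_df.columns) - set(EMG_CHANNELS)
        raise ValueError(
            f"EMG channel mismatch: missing {sorted(missing)}, "
            f"unknown {sorted(extra)}")
    mdf = pd.read_csv(d / "markers.csv", float_precision="round_trip")
    markers = {}
    for name in MARKER_NAMES:
        cols = [f"{name}_{ax}" for ax in "xyz"]
        if not all(c in mdf.columns for c in cols):
            raise ValueError(f"markers.csv missing columns for {name!r}")
        arr = mdf[cols].to_numpy(dtype=float)
        for j in range(3):
            arr[:, j] = _fill_gaps(arr[:, j], meta["fs_kin"], f"{name}[{'xyz'[j]}]")
        markers[name] = arr
    cop = pd.read_csv(d / "cop.csv", float_precision="round_trip")[["ml", "ap"]].to_numpy(dtype=float)
    beam = meta.get("beam")
    return TrialRecording(
        emg=emg_df.to_numpy(dtype=float).T,
        fs_emg=float(meta["fs_emg"]),
        markers=markers,
        fs_kin=float(meta["fs_kin"]),
        cop=cop,
        fs_cop=float(meta["fs_cop"]),
        beam=None if beam is None else BeamGeometry(beam["center_ml"], beam["width"]),
        meta=TrialMeta(meta["subject"], meta["time_point"], meta["condition"],
                       meta["dominant_side"]),
    )


def write_results(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Tidy long-format results with deterministic column order."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing columns {missing}")
    tab = table[RESULT_COLUMNS].copy()
    if len(tab) and not pd.api.types.is_numeric_dtype(tab["value"]):
        raise ValueError("results 'value' column must be numeric")
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    tab.to_csv(out, index=False)
    return out


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- ground truth sidecars -------------------------------------------------

def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    payload = {
        "W_true": gt.W_true.tolist(),
        "profiles": [dataclasses.asdict(p) for p in gt.profiles],
        "right_hs": gt.right_hs.tolist(),
        "left_hs": gt.left_hs.tolist(),
        "foot_centers": {k: v.tolist() for k, v in gt.foot_centers.items()},
        "ds_frac": gt.ds_frac,
        "foot_width": gt.foot_width,
        "beam_halfwidth": gt.beam_halfwidth,
        "divergence_gain": gt.divergence_gain,
        "seed": gt.seed,
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload))
    return p


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        W_true=np.array(d["W_true"]),
        profiles=tuple(SynergyProfile(**p) for p in d["profiles"]),
        right_hs=np.array(d["right_hs"]),
        left_hs=np.array(d["left_hs"]),
        foot_centers={k: np.array(v) for k, v in d["foot_centers"].items()},
        ds_frac=d["ds_frac"],
        foot_width=d["foot_width"],
        beam_halfwidth=d["beam_halfwidth"],
        divergence_gain=d["divergence_gain"],
        seed=d["seed"],
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Materialize a synthetic cohort to disk, ground truth alongside."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for spec in cohort.trials:
        name = f"{spec.meta.subject}_{spec.meta.time_point}_{spec.meta.condition}"
        tdir = out / name
        write_trial(spec.make(), tdir)
        write_ground_truth(spec.ground_truth(), tdir / "ground_truth.json")
        entries.append({
            "subject": spec.meta.subject,
            "time_point": spec.meta.time_point,
            "condition": spec.meta.condition,
            "path": name,
        })
    (out / "manifest.json").write_text(json.dumps(
        {"seed": cohort.seed, "trials": entries}, indent=1))
    return out


def read_manifest(cohort_dir: str | Path) -> list[dict]:
    d = Path(cohort_dir)
    return json.loads((d / "manifest.json").read_text())["trials"]
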