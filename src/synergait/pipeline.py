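"""Cohort orchestration: trials -> per-trial metrics -> statistics tables.

``run_trial`` turns one recording into gait metrics, a local divergence
exponent, and a stride-normalized EMG block. ``run_cohort`` assembles the
3 time-points x 2 conditions design per subject, extracts synergies with
muscle weightings fixed across a subject's six blocks, scores FWHM/CoA per
block, and runs the statistical layer (two-way repeated-measures ANOVAs,
one-way ANOVAs for the narrow-base-only performance measures, Holm paired
post-hocs, and the Harrison-Kanji circular ANOVA for CoA angles).

A run is reproducible from (data, config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import events as ev_mod
from . import metrics as met_mod
from . import stability as stab_mod
from . import synergy as syn_mod
from . import stats as stats_mod
from .synthetic import Cohort
from .types import CONDITIONS, TIME_POINTS, GaitEvents, TrialRecording

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters; fully serializable for provenance logging."""

    trim_seconds: float = 30.0
    n_strides: int = 160
    samples_per_stride: int = 100
    hp_cutoff: float = 50.0
    notch_base: float = 50.0
    notch_bw: float = 1.0
    lp_cutoff: float = 20.0
    k: int = 5
    restarts: int = 50
    max_iter: int = 1000
    tol: float = 1e-6
    vaf_min: float = 0.85
    embed_dim: int = 5
    delay: int = 10
    exclusion: int = 50
    fit_window: int = 50
    alpha: float = 0.05
    seed: int = 0
    do_synergies: bool = True
    do_lde: bool = True
    reference_W: Optional[list] = None  # orders synergies when given

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class TrialResult:
    meta: object
    events: GaitEvents
    metrics: met_mod.GaitMetricRow
    stability: Optional[stab_mod.StabilityResult]
    emg_block: Optional[emg_mod.StrideNormalizedEMG]

    def metric_dict(self) -> dict[str, float]:
        d = self.metrics.as_dict()
        if self.stability is not None:
            d["lde"] = self.stability.lde
        return d


def run_trial(trial: TrialRecording, config: RunConfig) -> TrialResult:
    """Single-trial pipeline: trim, events, metrics, LDE, E block."""
    import time

    t_start = time.perf_counter()
    stage = "trim"
    try:
        trimmed = ev_mod.trim_initial(trial, config.trim_seconds)
        stage = "events"
        events = ev_mod.detect_events(trimmed)
        stage = "gait_metrics"
        row = met_mod.gait_metrics(trimmed, events, n_strides=config.n_strides)
        stab = None
        if config.do_lde:
            stage = "lde"
            strides = events.strides(config.n_strides)
            stab = stab_mod.lde_from_trial(
                trimmed, strides,
                per_stride=config.samples_per_stride,
                dim=config.embed_dim, delay=config.delay,
                exclusion=config.exclusion, fit_window=config.fit_window,
            )
        block = None
        if config.do_synergies:
            stage = "emg_preprocess"
            block = emg_mod.preprocess(
                trimmed.emg, trimmed.fs_emg, events,
                hp_cutoff=config.hp_cutoff, notch_base=config.notch_base,
                notch_bw=config.notch_bw, lp_cutoff=config.lp_cutoff,
                samples_per_stride=config.samples_per_stride,
                n_strides=config.n_strides,
            )
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed for "
                           f"{trial.meta.subject}/{trial.meta.time_point}/"
                           f"{trial.meta.condition}: {exc}") from exc
    log.info(
        "trial %s/%s/%s done in %.2f s (hp=%g notch=%g/%g lp=%g, "
        "%d strides)", trial.meta.subject, trial.meta.time_point,
        trial.meta.condition, time.perf_counter() - t_start,
        config.hp_cutoff, config.notch_base, config.notch_bw,
        config.lp_cutoff, config.n_strides)
    return TrialResult(meta=trial.meta, events=events, metrics=row,
                       stability=stab, emg_block=block)


@dataclass
class CohortResult:
    metrics: pd.DataFrame                 # tidy long format
    anovas: dict[str, list[stats_mod.AnovaResult]]
    circular_anovas: dict[str, list[stats_mod.AnovaResult]]
    posthocs: dict[str, pd.DataFrame]
    synergy_models: dict[str, syn_mod.SynergyModel] = field(default_factory=dict)
    dropped_subjects: list[str] = field(default_factory=list)

    def metric_names(self) -> list[str]:
        return sorted(self.metrics["metric"].unique())

    def wide(self, metric: str) -> pd.DataFrame:
        sub = self.metrics[self.metrics["metric"] == metric]
        return sub.pivot_table(index="subject",
                               columns=["time_point", "condition"],
                               values="value", observed=True)

    def summary(self) -> str:
        lines = [f"Cohort: {self.metrics['subject'].nunique()} subjects, "
                 f"{len(self.metric_names())} metrics"]
        if self.dropped_subjects:
            lines.append(f"dropped (incomplete): {', '.join(self.dropped_subjects)}")
        for metric, results in sorted(self.anovas.items()):
            lines.append(metric)
            for r in results:
                lines.append("  " + r.summary())
        for metric, results in sorted(self.circular_anovas.items()):
            lines.append(metric + " (circular)")
            for r in results:
                lines.append("  " + r.summary())
        return "\n".join(lines)


def _subject_synergy_rows(
    blocks: dict[tuple[str, str], np.ndarray],
    config: RunConfig,
    subject_seed: int,
) -> tuple[list[dict], syn_mod.SynergyModel]:
    model, A_blocks = syn_mod.fit_fixed_W(
        blocks, config.k, restarts=config.restarts,
        max_iter=config.max_iter, tol=config.tol, seed=subject_seed,
    )
    # stable synergy labels: match to the reference weightings when given,
    # otherwise order by circular mean CoA of the whole-trial activations
    if config.reference_W is not None:
        perm = syn_mod.match_synergies(np.asarray(config.reference_W, float),
                                       model.W)
    else:
        coas = []
        for j in range(config.k):
            try:
                coas.append(stats_mod.circ_mean(
                    syn_mod.coa_per_stride(model.A[j], config.samples_per_stride)))
            except ValueError:
                coas.append(np.inf)
        perm = np.argsort(coas, kind="stable")
    rows = []
    for (tp, cond), A in A_blocks.items():
        timing = syn_mod.activation_timing(A[perm], config.samples_per_stride)
        for j in range(config.k):
            rows.append({"time_point": tp, "condition": cond,
                         "metric": f"fwhm_s{j + 1}", "value": timing.fwhm[j]})
            rows.append({"time_point": tp, "condition": cond,
                         "metric": f"coa_s{j + 1}", "value": timing.coa[j]})
    return rows, model


def run_cohort(
    trials: Cohort | Iterable[tuple[object, TrialRecording]],
    config: RunConfig,
) -> CohortResult:
    """Full cohort analysis. Subjects lacking the complete 3 x 2 design are
    dropped (logged); fewer than two complete subjects is an error."""
    # group trial providers by subject
    providers: dict[str, dict[tuple[str, str], object]] = {}
    if isinstance(trials, Cohort):
        for spec in trials.trials:
            providers.setdefault(spec.meta.subject, {})[
                (spec.meta.time_point, spec.meta.condition)] = spec.make
    else:
        for meta, trial in trials:
            providers.setdefault(meta.subject, {})[
                (meta.time_point, meta.condition)] = (lambda tr=trial: tr)

    full = [(tp, c) for tp in TIME_POINTS for c in CONDITIONS]
    dropped = [s for s, blocks in providers.items()
               if set(blocks) != set(full)]
    for s in dropped:
        log.warning("subject %s dropped: incomplete design", s)
    subjects = [s for s in providers if s not in dropped]
    if len(subjects) < 2:
        raise ValueError(f"need >= 2 complete subjects, have {len(subjects)}")

    records: list[dict] = []
    models: dict[str, syn_mod.SynergyModel] = {}
    for si, subj in enumerate(subjects):
        blocks: dict[tuple[str, str], np.ndarray] = {}
        for key in full:
            tr = providers[subj][key]()
            res = run_trial(tr, config)
            for metric, value in res.metric_dict().items():
                records.append({"subject": subj, "time_point": key[0],
                                "condition": key[1], "metric": metric,
                                "value": float(value)})
            if config.do_synergies and res.emg_block is not None:
                blocks[key] = res.emg_block.E
            del tr
        if config.do_synergies and blocks:
            rows, model = _subject_synergy_rows(
                blocks, config, subject_seed=config.seed + 1000 + si)
            models[subj] = model
            for r in rows:
                records.append({"subject": subj, **r,
                                "value": float(r["value"])})
    metrics = pd.DataFrame.from_records(
        records, columns=["subject", "time_point", "condition", "metric", "value"])

    anovas: dict[str, list[stats_mod.AnovaResult]] = {}
    circ: dict[str, list[stats_mod.AnovaResult]] = {}
    posthocs: dict[str, pd.DataFrame] = {}
    for metric in sorted(metrics["metric"].unique()):
        sub = metrics[metrics["metric"] == metric]
        if metric.startswith("coa_"):
            piv = sub.pivot_table(index="subject",
                                  columns=["time_point", "condition"],
                                  values="value", observed=True)
            angles, fa, fb = [], [], []
            for (tp, cond) in piv.columns:
                angles.extend(piv[(tp, cond)].to_numpy())
                fa.extend([tp] * len(piv))
                fb.extend([cond] * len(piv))
            circ[metric] = stats_mod.circ_anova2(
                np.asarray(angles), np.asarray(fa), np.asarray(fb))
            continue
        narrow_only = metric in ("fpe_mean", "pct_in_beam")
        if narrow_only:
            data = sub[sub["condition"] == "narrow"]
            res = stats_mod.rm_anova(data, "value", "time_point", "subject")
        else:
            data = sub
            res = stats_mod.rm_anova(data, "value",
                                     ["time_point", "condition"], "subject")
        anovas[metric] = res
        training = next((r for r in res if r.effect == "time_point"), None)
        inter = next((r for r in res if "*" in r.effect), None)
        if ((training is not None and training.p < config.alpha)
                or (inter is not None and inter.p < config.alpha)):
            if narrow_only:
                posthocs[metric] = stats_mod.paired_posthocs(
                    data, "value", "time_point", "subject")
            else:
                for cond in CONDITIONS:
                    posthocs[f"{metric}[{cond}]"] = stats_mod.paired_posthocs(
                        data[data["condition"] == cond], "value",
                        "time_point", "subject")
    return CohortResult(metrics=metrics, anovas=anovas, circular_anovas=circ,
                        posthocs=posthocs, synergy_models=models,
                        dropped_subjects=dropped)


def save_report(result: CohortResult, out_dir: str | Path,
                config: Optional[RunConfig] = None) -> Path:
    from .dataio import write_results

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results(result.metrics, out / "metrics.csv")
    rows = []
    for metric, results in {**result.anovas, **result.circular_anovas}.items():
        for r in results:
            rows.append({"metric": metric, "effect": r.effect, "F": r.F,
                         "df_num": r.df_num, "df_den": r.df_den, "p": r.p,
                         "epsilon": r.epsilon, "gg_applied": r.gg_applied})
    pd.DataFrame(rows).to_csv(out / "anova.csv", index=False)
    for name, tab in result.posthocs.items():
        safe = name.replace("[", "_").replace("]", "")
        tab.to_csv(out / f"posthoc_{safe}.csv", index=False)
    (out / "summary.txt").write_text(result.summary() + "\n")
    if config is not None:
        (out / "config.json").write_text(config.to_json())
    return out
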