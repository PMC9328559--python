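# synergait

Gait-stability and muscle-synergy analysis for treadmill walking, built for
studies that compare normal and narrow-base (beam-constrained) walking
across repeated measurement points — e.g. before and after balance
training. It is aimed at movement scientists who record surface EMG,
optical markers and force-plate center of pressure on a treadmill and want
a tested, reproducible pipeline from raw streams to statistics tables.

## What it computes

**Gait events.** Heel-strikes from anterior extrema of the AP center of
pressure (the treadmill "butterfly"), with leg assignment from foot
kinematics — necessary in narrow-base walking, where both feet share the
midline and the butterfly collapses. Strides are dominant-leg heel-strike
to heel-strike; the first 30 s are discarded and 160 strides analyzed.

**Gait performance.** Step width mean/SD; foot-placement error (ML
overshoot of the furthest foot edge beyond a 12 cm projected beam; zero if
the whole foot is inside) and the percentage of steps inside the beam;
trunk CoM peak-to-peak ML displacement, its variability, and mean absolute
ML velocity per stride.

**Local dynamic stability.** The local divergence exponent λ of trunk CoM
velocity: 160 strides time-normalized to 16000 samples, delay-embedded
(5 dimensions, 10-sample delay), nearest-neighbor log-divergence averaged
and fitted over half a stride,

    λ = slope of ⟨ln d(t)⟩ over offsets [0, 50) samples  (ln/stride).

**Muscle synergies.** Surface EMG (11 channels, 2000 Hz) is high-passed
(50 Hz, 4th order), notch-filtered at 50 Hz and harmonics (1 Hz wide),
Hilbert-rectified and low-passed (20 Hz), max-normalized per channel per
trial, and stride-normalized to 100 samples, giving E (11 × strides·100).
Non-negative matrix factorization with Lee–Seung multiplicative updates
(50 restarts, ≤1000 iterations, 1e-6 tolerance) solves E ≈ W·A; the
number of synergies is the smallest k with VAF ≥ 0.85, and for group
comparisons W is fixed across a subject's conditions and time-points by
factorizing the concatenated data. Activation profiles are summarized per
stride by FWHM (samples above half the min-subtracted maximum) and CoA
(circular first-moment angle of the profile over the gait cycle).

**Statistics.** Two-way repeated-measures ANOVAs (Training × Condition)
with Mauchly screening and Greenhouse–Geisser correction, Holm-corrected
paired post-hocs (Pre vs Post1, Pre vs Post2), and the Harrison–Kanji
two-factor ANOVA for the circular CoA data.

A synthetic-cohort generator (`synergait.synthetic`) produces all of the
above inputs with known ground truth — synergy weightings, activation
bumps, heel-strike times, foot placements, tunable trunk divergence — so
the whole pipeline is testable without any recordings.

## Worked example

```python
import synergait as sg
from synergait import emg as em, synergy as sy, stability as st

gt = sg.make_ground_truth(n_strides=40, lead_in=5.0, seed=2)   # known truth
trial = sg.gen_trial(gt, sg.TrialMeta("S01", "Pre", "narrow"), snr_db=20.0)

trimmed = sg.trim_initial(trial, 5.0)
events = sg.detect_events(trimmed)
row = sg.gait_metrics(trimmed, events, n_strides=40)

res = st.lde_from_trial(trimmed, events.strides(40))
E = em.preprocess(trimmed.emg, trimmed.fs_emg, events, n_strides=40)
model = sy.nnmf(E.E, 5, restarts=10, seed=0, muscles=E.muscles)
```

This prints (via `row.as_dict()`, `res.lde`, `model.summary()`):

```
step_width_mean  0.1206
step_width_sd    0.0104
com_disp_mean    0.0550
com_disp_sd      0.0001
com_vel_mean     0.1017
fpe_mean         0.0504
pct_in_beam      0.0000
lde              0.8281   # ln-units per stride
SynergyModel: k=5, VAF=0.8807
```

Reading it: the generator placed feet 12 cm apart (recovered 0.1206 ±
0.0104 m); this trial walks a 12 cm-wide foot on a 12 cm beam at normal
step width, so the lateral edge overshoots by ~5 cm (`fpe_mean 0.0504`)
and no step lands wholly inside (`pct_in_beam 0`). The trunk oscillates
5.5 cm peak-to-peak with an LDE of 0.83 ln/stride, and five synergies
explain 88% of the EMG variance; their matched cosines against the
generator's true weightings are `[0.953 0.994 0.966 0.889 0.995]`.

Cohort-scale analysis goes through `synergait.pipeline`:

```python
cohort = sg.gen_cohort(n_subjects=10, seed=1)          # 3 time-points x 2 conditions
result = sg.run_cohort(cohort, sg.RunConfig())
print(result.summary())                                # ANOVA tables per metric
```

or from the shell, for cohorts materialized on disk as CSV + JSON:

```
synergait simulate --out cohort/ --subjects 10 --seed 1
synergait run-all --data cohort/ --out results/ --seed 1
synergait run-all --data cohort/ --out results_k6/ --seed 1 --k 6   # sensitivity
```

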