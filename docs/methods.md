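# Methods

`synergait` analyzes treadmill-walking recordings made under two balance
conditions — unconstrained ("normal") walking and narrow-base walking inside
a projected 12 cm beam — at three measurement points (Pre, Post1, Post2).
Its outcome measures fall into three families: spatiotemporal gait
performance (step width and variability, foot-placement error and
percentage of steps inside the beam, trunk center-of-mass excursion and
velocity), local dynamic stability (the local divergence exponent of trunk
motion), and neuromuscular coordination (muscle-synergy activation duration
and timing). A synthetic-cohort generator with full ground truth stands in
for the human recordings, so every stage is testable end to end.

## Trial model and conventions

A trial holds 11-channel surface EMG at 2000 Hz (channels TAD, VLD, GLD,
SOD, PLD, RFD, RFN, BFD, BFN, GMD, GMN — five unilateral shank/thigh
muscles of the dominant leg plus three bilateral muscle pairs), marker
trajectories at 50 Hz (trunk cluster centroid, per-foot reference point and
medial/lateral foot edges), a 2-D center-of-pressure (CoP) trace, and —
for narrow-base trials — the beam geometry. Axes: mediolateral (ML) = x,
anterior-posterior (AP) = y, vertical = z, meters; time in seconds from
trial start; intervals half-open. The first 30 s of every trial are
discarded (habituation) and all variables are computed over the first 160
complete strides.

## Gait events

Heel-strikes are placed at anterior extrema of the AP CoP component (the
treadmill "butterfly" geometry): the AP trace is zero-phase low-passed at
10 Hz (symmetric peaks are not biased) and peaks are picked with a 0.4 s
refractory separation. Because the butterfly collapses in narrow-base
walking, events are not lateralized from the CoP; each event is assigned to
the foot whose reference marker is more anterior at that instant, and
left/right alternation is enforced (isolated violations drop the
lower-margin event and are logged; more than 10% violations abort the
trial). A stride runs from one dominant-leg heel-strike to the next and
must contain exactly one contralateral heel-strike.

Toe-off is not observable from these data; for the support-phase summary
only, it is approximated from the CoP ML transfer: the transfer crosses the
midline roughly midway through double support, so toe-off is extrapolated
as `2*t_cross - t_heelstrike`. Each stride then decomposes into double
support 1 + ipsilateral single support + double support 2 + contralateral
single support, which sum to 100% by construction. This estimate is exact
for a symmetric linear CoP transfer and is used for no other metric.

## Gait performance metrics

Step width is |ML_left − ML_right| pairing each new placement (foot
reference marker at the heel-strike instant) with the most recent
contralateral placement; mean and SD are taken over the analyzed strides.
Foot-placement error (narrow trials) is the ML overshoot of the
furthest-protruding foot edge beyond the nearer beam edge, zero when the
whole foot is inside; the percentage of steps in the beam counts
placements with both edges inside. Trunk CoM is the trunk-cluster centroid;
per stride we take the peak-to-peak ML displacement and the mean absolute
ML velocity (central differences; a signed mean would vanish on a
treadmill). All metrics are invariant to a rigid ML translation of the
scene.

## Local divergence exponent

The trunk ML velocity over 160 strides is time-normalized to 100 samples
per stride (16000 samples, amplitudes untouched so between-stride
variability is preserved), delay-embedded with 5 dimensions at a 10-sample
delay, and each state's nearest Euclidean neighbor is found under a
temporal (Theiler) exclusion of half a stride — a guard the source method
leaves unspecified; half a stride suppresses trivially-near-in-time
neighbors at gait periodicity. The mean log distance between each pair is
tracked over increasing offsets (pairs leaving the series are dropped;
offsets retaining under half the pairs are truncated), distances are
floored at 1e-12 of the series scale so exactly periodic series stay
finite, and the LDE is the least-squares slope over offsets [0, 50),
reported in ln-units per stride.

Validity is checked two ways. (1) On a Lorenz x-series (σ=10, ρ=28,
β=8/3; dt=0.01, N=14000, exclusion two mean orbital periods) the fitted
slope is compared with the largest Lyapunov exponent from an independent
Benettin two-trajectory oracle. For such a clean deterministic benchmark
the first ~embedding-span of offsets carries a nearest-neighbor selection
transient (the offset-0 distance is a minimum over all candidates, an
extreme-value bias that decays as the embedding windows separate), so the
benchmark fit uses the linear scaling region starting at offset 60 —
standard practice when locating the scaling region of a noiseless system.
Gait signals are fitted from offset 0 as specified for the gait method;
their noise floor removes the bias. (2) On synthetic gait, the LDE must
increase strictly across a divergence-gain sweep (below).

## EMG preprocessing and synergies

The filter chain is: 50 Hz high-pass (4th-order Butterworth), band-stops at
50 Hz and all harmonics below Nyquist (1 Hz wide, 1st order), envelope as
the modulus of the Hilbert analytic signal low-passed at 20 Hz — all
zero-phase (forward-backward). Forward-backward pads are set to six times
the filter's characteristic ring (6/bandwidth seconds for the notches):
scipy's default pad is far too short for 1 Hz-wide stops and breaks
zero-phase symmetry at the percent level. Envelopes are normalized to the
per-channel per-trial maximum, and each stride is linearly resampled onto
100 points (half-open grid anchored at dominant-leg heel-strikes), giving
the nonnegative matrix E (11 × strides·100).

Synergies solve E ≈ W·A with Lee–Seung multiplicative updates for the
squared Frobenius objective: 50 random restarts (uniform(0,1] inits scaled
to the data), at most 1000 iterations, stopping when the relative
per-iteration objective decrease falls below 1e-6 (the objective is the
monitored quantity; the tolerance's referent was an open choice). The best
restart is kept; the W/A scale ambiguity is fixed by max-normalizing W
columns. VAF = 1 − ‖E−WA‖²_F/‖E‖²_F. The number of synergies is the
smallest k reaching VAF ≥ 0.85; the sweep warm-starts k from the best
(k−1) solution padded with a small random component, which keeps the VAF
curve monotone. For group analysis the muscle weightings are fixed across
a subject's 3 time-points × 2 conditions by factorizing the
column-concatenated blocks once and slicing A back per block; a k=6
sensitivity re-run is a pure configuration change.

Activation timing per stride: FWHM is the count of samples above half the
min-subtracted maximum (0 for a flat profile, logged); the thresholding is
per stride, and per-stride values are averaged arithmetically. CoA is the
angle of the circular first moment of the profile (sample t at angle
2πt/100, dominant heel-strike = 0), averaged across strides with the
circular mean. FWHM is baseline- and scale-invariant; CoA is
scale-invariant and shift-equivariant. Synergy order is arbitrary in NNMF,
so cohort tables order synergies by matching to a reference weighting
matrix when one is supplied (synthetic runs use the generator's truth) and
otherwise by ascending circular-mean CoA.

## Statistics

Two-way repeated-measures ANOVAs (Training × Condition) are run on every
linear metric, one-way Training ANOVAs on the narrow-base-only performance
measures, via pingouin. For each effect with more than one numerator df,
Mauchly's test is run (main effects on data collapsed over the other
factor); when sphericity is rejected at p < 0.05 the Greenhouse–Geisser ε
scales both degrees of freedom and the corrected p is reported. Post-hoc
paired t-tests compare Pre vs Post1 and Pre vs Post2 with Holm's
step-down correction (family of two), run when the Training effect or the
interaction is significant at α = 0.05.

CoA angles get the Harrison–Kanji two-factor ANOVA for circular data,
implemented from the published equations: resultant lengths are decomposed
by factor level and cell; with estimated concentration κ̂ > 2 (Fisher's
approximation with the small-sample correction), corrected F statistics
are used (factor effects scaled by 1/(1 − 1/(5κ) − 1/(10κ²)); the
interaction F is uncorrected) against the n − pq residual; otherwise a
χ² approximation scaled by 2/(1 − A₁(κ)²) applies with p−1, q−1 and
(p−1)(q−1) degrees of freedom. A zero-residual design returns F = 0,
p = 1; a near-zero resultant in any cell triggers a warning, as the test's
assumptions are then violated. Normality screening and transformation
policy are left to standard tooling and recorded in the run log, not
re-implemented.

## The synthetic cohort

Stride durations are log-normal with mean 1.08 s (3.5 km/h treadmill) and
3% CV; contralateral heel-strikes fall at 50% of the cycle; double support
defaults to 10% of the stride per side. Foot placements are ±width/2 with
independent Gaussian jitter (per-placement SD = step-width SD/√2); normal
walking defaults to a 12 cm step width, narrow-base to 5 cm against a
12 cm beam, foot width 10 cm.

EMG is built from five synergies with physiologically arranged weightings
(dominant stance/push-off, dominant weight acceptance, non-dominant
stance, and two pre-heel-strike hamstring synergies) and Gaussian
activation bumps (σ 4.5–6% of the cycle, amplitudes balancing per-synergy
power), with 5% per-stride amplitude and 1-sample center jitter. Each
channel's envelope amplitude-modulates an independent 20–450 Hz Gaussian
carrier; white noise sets the SNR (20 dB default) and an optional 50 Hz
sinusoid emulates line interference. Crucially, a per-muscle residual term
— half-wave-rectified 15 Hz-smooth bursts at 1.0× each muscle's envelope
RMS — models muscle activity outside the synergy model. Without it the
generated data are nearly exactly rank-5 and a 3–4-synergy fit already
explains >90% of the variance, which no real surface-EMG dataset does;
with it, five synergies account for ≈88% of the variance and four for
≈84%, so the 85% criterion selects five, matching the regime the method
is designed for. The residual is the main driver of the remaining
weighting-recovery error (matched cosines ≈0.95–0.98 at 160 strides).

Trunk ML motion is a two-harmonic function of gait phase whose amplitude
and phase are perturbed by slow (τ = 2 s) unit-variance noise scaled by
the divergence gain; at gain 0 the trajectory is an exact function of
phase. All markers carry 0.1 mm RMS sensor noise (typical active-marker
precision); without it a gain-0 trial is numerically periodic and its
log-divergence measures interpolation error rather than dynamics. The CoP
AP component peaks at every heel-strike; the ML component transfers
linearly between stance feet over the double-support window, with optional
measurement noise (2 mm RMS in the robustness checks).

Cohorts place 3 time-points × 2 conditions per subject with between-subject
step-width (SD 8 mm) and bump-center (SD 1.5% cycle) offsets; imposed
condition/time effects (step-width shifts, bump width/center changes,
divergence-gain offsets) are recorded as ground truth. What the generator
does not emulate: nonstationary electrode impedance, crosstalk between
channels, movement artifacts below 20 Hz, AP/vertical balance dynamics,
foot rotation (edges move rigidly with the reference point), and real
inter-muscle correlation structure beyond the synergy model — so passing
tests demonstrate correctness of the computations under the stated model,
not robustness to every artifact of real recordings.

## Problem sizes and numerical choices

Single-trial checks run at full study scale (160 strides, 50 NNMF
restarts). Cohort-level simulations are scaled to desk size, chosen once:
the type-I control uses 200 kinematics-only null cohorts of 10 subjects ×
20 strides (step width, two-way RM-ANOVA; the Training rejection rate at
α = 0.05 must lie in [0.02, 0.08]); the effect-recovery cohort uses 20
subjects × 40 strides with 3 NNMF restarts. The k-selection sweep inside
the acceptance path uses 10 restarts per k (warm-started). Degenerate
inputs: flat activation profiles have FWHM 0; zero-resultant circular
means and CoAs raise; all-zero EMG channels raise naming the channel;
marker gaps ≤ 0.2 s are linearly interpolated and logged, longer gaps
raise. Determinism: every stochastic component draws from
`numpy.random.default_rng` seeded from explicit (seed, salt) pairs, and a
run is bit-reproducible from (data, config, seed).

## Known limitations

The CoP-based event detector assumes a treadmill with a single force
plate and anterior CoP extrema at heel-strike; it has no force threshold
and will mislabel pathological gait with missing anterior excursions. The
toe-off approximation is only as good as the symmetry of the CoP
transfer. The Harrison–Kanji small-κ branch follows the χ² form with
uncorrected degrees of freedom; toolbox implementations differ here, and
CoA data concentrated enough to be analyzed at all use the F branch in
practice. LDE values depend on the (specified) embedding and fit window
and are comparable only within those choices.
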