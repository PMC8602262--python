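# Methods

## The closed-loop assay

All series live on a uniform 5 ms grid (200 Hz tail tracking).  The tail
trace is the cumulative sum of eight segment angles in radians.  *Vigor* is
its causal sliding standard deviation over a trailing 50 ms window
(population SD, so a fast sinusoid of amplitude A plateaus at A/√2); it is
converted to an estimated forward velocity by a multiplier calibrated so the
median estimate over in-bout samples is 20 mm/s, the free-swimming bout
speed.  Bouts are flagged online wherever the estimate exceeds 2 mm/s
(strict inequality, no hysteresis; refined segmentation happens offline).

During bouts the estimated velocity is subtracted from the 10 mm/s forward
grating command.  Perturbations of this reafference come in three families
and their stated parameter sets: gains {0, 0.33, 0.66, 1, 1.33, 1.66, 2},
lags {0, 75, 150, 225, 300, ∞} ms plus shunted variants, and eight
four-digit gain-drop profiles over 75 ms segments of the first 300 ms of the
bout.  **Lag semantics.** A lag is implemented as a time shift of the
in-bout velocity stream: the delayed reafference persists for exactly the
lag past bout offset (the source of "excess reafference after the bout"),
while the shunted variant is truncated at the offset.  Gain and gain-drop
conditions gate the current velocity and therefore stop at the offset;
gain-drop profiles revert to gain 1 past 300 ms.  Under these semantics the
redundant family lists collapse to 18 functionally unique conditions —
gain 1 ≡ lag 0 ≡ profile 1111, gain 0 ≡ infinite lag, and each shunted lag
coincides with a gain-drop profile (e.g. 150 ms shunted ≡ 0011).  The
equivalences are exact for a piecewise-constant (binary) bout velocity,
which is what the controller emits; deduplication is performed by comparing
the induced mappings on a binary bout-shaped probe rather than by symbolic
rules.

Protocols share a 30 s trial (7.5 s static, 15 s forward at 10 mm/s, 7.5 s
static) and a calibration/pre-adaptation/adaptation/post-adaptation phase
structure of 10/10/N/M trials: N = 210, M = 10 for the acute-reaction
protocol (per-bout conditions drawn uniformly from the 18) and the long-term
adaptation protocol (225 ms non-shunted lag for the lag-trained group);
N = 50, M = 50 for Purkinje-cell imaging; the whole-brain protocol prepends
120 s of blank screen, uses N = 40 with per-bout draws from
{normal, open-loop}, omits the post phase and adds two 350 ms reverse
pulses 5 and 10 s after each moving period.

## The feedback controller

Eight parameters (ω_f, ω_r, τ_s, thr, ω_s, ω_m, τ_m, ω_i), a fixed 220 ms
sensory delay, and a binary 20 mm/s output.  Per 5 ms step, with u the shown
grating velocity 220 ms earlier:

    s_in = ω_f·max(u,0) − ω_r·max(−u,0)
    V ← clip_[0,1]( V·e^{−dt/τ_s} + s_in·(1 − e^{−dt/τ_s}) )
    D = max(0, V + ω_s·b_prev − ω_i·M)
    b = 1 if D ≥ thr else 0
    M ← min(1, M·e^{−dt/τ_m} + ω_m·b·(1 − e^{−dt/τ_m}))

The exponential-Euler update is exact for input held constant over a step,
so sub-threshold trajectories coincide with the closed-form linear-ODE
solutions to machine precision; this is the oracle the tests check.  The
self-excitation term uses the previous step's bout state, providing the
hysteresis that keeps bouts alive; the delay buffer is initialized with the
pre-trial static value (0 mm/s).  Perturbing the shown grating at time t
first changes V (and hence the motor drive D) exactly 220 ms later; the
binary output flips only when D crosses the threshold, so divergence
latency is measured on the motor-drive trace.

**Reference parameters.**  ω_f = 0.045 and ω_r = 0.015 per mm/s, τ_s = 0.5 s,
thr = 0.25, ω_s = 0.12, ω_m = 1.3, τ_m = 2.4 s, ω_i = 0.6.  This set was
chosen (hand-guided search over the qualitative constraints) so the model
reproduces the acute-reaction ordering relations with ≥ 11% margins: bout
duration decreasing in gain and increasing in lag; interbout duration
V-shaped in gain (open-loop and gain-2 interbouts both exceed normal);
non-shunted > shunted interbouts at 300 ms lag; longer bouts under 0111 than
1110; shorter interbouts under 1100 than 0011 — with realistic magnitudes
(normal bouts ≈ 300 ms, ~12 bouts per 15 s trial, all bouts within
0.1–1 s).  The regime that satisfies all constraints simultaneously needs a
weak reverse weight (graded depletion of the sensory drive distinguishes
gains ≥ 1) and a slow, strong motor integrator (residual tiredness after
long open-loop bouts lengthens their interbouts).

**Model-test trial.**  300 ms static + 9.7 s forward grating; bout 1 gets
normal reafference, bout 2 the probed condition; the trial ends at the
third bout onset, which validates the (bout 2, interbout 2) output; without
a third bout the trial yields nothing.  One deterministic evaluation per
condition builds the 36-value summary (18 bout + 18 interbout durations).

## Fitting

The objective is mean(|model − target| / target) over the 36 summary
entries; conditions with no model output contribute a fixed pessimistic
penalty of 2.0 (the original procedure silently drops such trials, but an
optimizer needs a finite value).  Datasets split per condition 50/50 at
random (odd sizes favor training).  The optimizer is a seeded genetic
algorithm — population 64, tournament size 3, uniform crossover (p = 0.5),
per-gene Gaussian mutation (p = 0.3) with the scale annealed geometrically
from 15% to 0.5% of the bound range over 300 generations, elitism 2 — over
log10-transformed parameters; bounds are τ ∈ [0.05, 20] s, weights and
threshold ∈ (10⁻³, 10].  All parameters are searched on the log scale
because the behaviorally correct weight regime (~10⁻² per mm/s) occupies a
vanishing fraction of a linear search volume; with linear weights the fit
stalls an order of magnitude short of the recovery criterion.  The GA is a
means, not the contribution: any derivative-free method reaching behavior
recovery (MAE ≤ 0.05 against a known model's table) is equivalent.
Parameter identifiability is *not* claimed — different parameter sets can
produce near-identical duration tables (see `examples/02_fit_controller.py`).

## Behavioral analysis

Tail traces are linearly interpolated to the 5 ms grid and z-scored; the raw
radian trace is kept because bout power is measured in rad².  A tail flick
is a section between adjacent local extrema with magnitude > 0.14 rad and
duration ≤ 100 ms; local extrema use strict inequalities with plateaus
assigned to their first sample.  Online bout intervals are snapped to the
first/last overlapping flick; bouts outside forward-grating motion, shorter
than 100 ms, or flanked by interbouts under 100 ms are excluded; the last
bout of a trial has no defined subsequent interbout.  Animals with ten
consecutive boutless trials are excluded.

Bout power: a 1.1 s section from 100 ms before onset (220 samples,
half-open window [−100, 1000) ms), post-offset samples zeroed, pre-onset
median subtracted, squared.  The ballistic/reactive split integrates the
profile (trapezoid) over [0, 220] and [220, 995] ms post-onset — the
reactive area therefore covers 0.775 s, not 0.78, because of the half-open
window.  Per-timepoint condition dependence uses Kruskal–Wallis with
Bonferroni threshold 0.05/220.

Adaptation metrics are block-of-ten differences of per-trial first-bout
values: acute reaction (first ten adaptation − pre-adaptation), reduction of
acute reaction (last ten − first ten adaptation), after-effect
(post-adaptation − pre-adaptation).  Trials without a first bout are
skipped, not zero-filled; a fish is *adapting* if the reduction is at most
−40 ms.  Group comparisons use the Mann–Whitney U test (exact for small
tie-free samples, normal approximation with tie correction otherwise;
two-sided by default).

## Imaging analysis

All filters are zero-phase order-4 Butterworth (the order is unstated in
the field's descriptions; 4 is the standard detrending choice), applied as
second-order sections for numerical stability at millihertz cutoffs.
Whole-brain traces (1.5 Hz): 0.56 Hz low-pass, subtraction of a 3.3 mHz
low-pass baseline, z-score.  Purkinje-cell traces (4–5 Hz): 3.3 mHz
high-pass, z-score.

Triggered averages take [−1, +4) s windows (first-bout responses: [−1, 1.2) s),
drop triggers with another trigger in the preceding second, NaN-mask samples
after a subsequent trigger, and subtract the pre-trigger mean.  Sensory and
motor scores are means of the average triggered trace over 0–4 s after
grating onsets and 0–2 s after bout onsets; the null permutes 23 s trace
sections 1000 times (the section count follows the trace length rather than
being fixed at 84, so the null generalizes to arbitrary session lengths),
and scores above the 95th null percentile are significant.  Sensory
classification takes priority: significant sensory → sensory; significant
motor and non-significant sensory → motor; otherwise unclassified.  In the
deterministic simulated sessions bouts are tightly grating-locked, so
motor-only units typically classify as sensory unless their bout train is
decoupled from the stimulus — a property of the synthetic behavior, not of
real larvae, whose bout timing jitters.

Time constants: the forward-rectified grating velocity is leaky-integrated
at each τ on the 0.5–10 s grid (0.5 s steps), convolved with a GCaMP6s
kernel (exponential, 1.8 s half-decay), and correlated with the trace; the
argmax τ wins, with sensors at τ ≤ 1.5 s and integrators above.  When the
trace has been preprocessed, the candidate regressors are passed through the
same filters: correlating a filtered trace against unfiltered regressors
biases τ̂ down by several grid steps at long τ.  Adaptation-related τ
changes are summarized as τ(end) − τ(begin) per ROI across ten-trial
blocks, smoothed with a 0.1 s Gaussian kernel, with decreases beyond 0.4 s
flagged.

ROI segmentation computes a per-plane correlation map (each voxel against
the mean of its eight in-plane neighbors, border voxels using available
neighbors), then greedily grows ROIs from the highest unassigned map value
(seed minimum 0.3); a candidate joins when its correlation with the current
ROI mean trace exceeds a threshold ramping linearly from 0.3 at the seed to
0.35 at 3 µm in-plane Euclidean distance.  ROIs outside 9–28 µm² are
discarded; traces are voxel sums.

Purkinje-cell responses: per-trial first-bout-triggered responses (0–1.2 s
means) feed four transition criteria (ten-trial block differences at the
four phase transitions).  The barcode null shuffles all non-calibration
trials jointly — one permutation yields all four criteria — 100,000 times;
criteria outside the [2.5, 97.5] null percentiles become '+'/'−', otherwise
'0'.  Under exchangeable responses the empirical probability of "0000" is
about 0.85 (the four criteria share blocks and are negatively correlated, so
the joint in-range probability exceeds the independent-test bound 0.95⁴ ≈
0.81).  Cluster enrichment compares within-fish barcode fractions across
groups per cluster (Kruskal–Wallis, 5%), reporting clusters whose mean
fraction reaches 2% in some group.

## Synthetic data

Tail kinematics render each scheduled bout as a 25 Hz oscillation in cosine
phase (the deflection starts at an extremum, so the first flick begins at
the true onset) under a 30 ms rise/fall envelope, amplitude 0.6 rad (flick
magnitudes ~1.2 rad, far above the 0.14 rad threshold), plus 0.01 rad
tracking jitter.  Scripted schedules draw bout durations ~N(350, 60²) ms and
interbouts ~N(800, 200²) ms inside moving periods; controller-driven
sessions take bout timing from the closed-loop simulation and render
kinematics on top.

The adapting cohort emulates recalibration as a parameter drift: adapting
fish ramp the tiredness-inhibition weight ω_i up by 60% across the
adaptation phase and keep it elevated afterwards (the adaptation is located
in the controller, not the environment), non-adapting fish hold parameters
fixed with a 20% blunted reverse weight, controls receive normal
reafference; all fish get 5% lognormal parameter jitter.  This yields
acute reaction ≈ +200 ms, reduction ≈ −60 ms and after-effect ≈ −45 ms in
adapting fish and ≈ 0 in controls.

Fluorescence traces are latent signals convolved with the indicator kernel,
scaled to unit SD, plus Gaussian noise of SD 1/SNR and a slow sinusoid
(amplitude 0.5, period 600 s) so detrending efficacy is measurable.
Sensor/integrator latents are built at the imaging frame rate with the same
integration operator the fitter uses — parameter recovery is then exact in
the noiseless limit, which is the point of a generative recovery test;
motor latents are built at the 200 Hz session rate (bouts are shorter than
an imaging frame) and sampled at frame times.  Barcode units place impulses
at first-bout onsets with per-trial amplitudes stepping by ±0.6 at the
four transitions (e.g. "0-0+": 1, 1, 0.4, 0.4, 1 across the five blocks).
Volumes plant Gaussian somata (σ = 1.2 µm; masks above 30% of peak, areas
inside 9–28 µm² at 0.6 × 0.6 µm voxels) with shared sparse-event time
courses on a noisy background at SNR 5.

## What passing tests do and do not show

Synthetic sessions are noise-free at the level of the behaving agent (the
controller is deterministic), bouts are more regular and more
stimulus-locked than real behavior, fluorescence noise is white and drift
sinusoidal, and somata are non-overlapping Gaussians.  Passing tests
therefore demonstrate the *correctness of the computations* — calibration,
condition algebra, delay-line behavior, fitting recovery, filter and
estimator behavior, null calibration of the shuffle tests — not the
robustness of the estimators to real-data pathologies (motion artifacts,
overlapping cells, correlated noise, behavioral drift).  Headline biological
quantities (fractions of barcode clusters in real cerebellum, empirical τ
distributions) depend on real larvae and are out of scope.

## Problem sizes and runtimes

Default test and acceptance runs use scaled problem sizes chosen for a
desktop machine: session generators default to full-length protocols (the
compiled loop simulates a 240-trial session in under a second), the
GA recovery test uses the default 64 × 300 budget (~10 s), barcode nulls use
10,000 shuffles in tests (100,000 remains the analysis default), and the
segmentation and cohort tests use 10 blobs and 20 fish per group.
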