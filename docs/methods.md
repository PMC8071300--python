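# Methods

## Problem and model

`lmrgait` classifies the terrain a walker is traversing — level walking
(LW), stair ascent/descent (SA/SD), ramp ascent/descent (RA/RD), labeled
1–5 — from sagittal-plane wearable-sensor signals: thigh accelerometer
(g_x, g_y in m/s²) and gyroscope (ω in deg/s) on each leg, plus a foot
pitch angle per foot, all sampled at 100 Hz. Walking cadence is paced by
a metronome (BPM 90/110/130, roughly 1.03/1.34/1.57 m/s); one stride
spans two beats, so the stride period is T = 120/BPM seconds.

The method has four stages.

### 1. Hip-angle estimation (complementary filter)

The thigh tilt seen by the accelerometer, θ_acc = atan2(g_y, g_x)
(degrees; the two-argument form is used because the quotient form loses
the quadrant), is unbiased but noisy during swing. The integrated
gyroscope angle θ_gyro = ∫ω dt (cumulative trapezoid, seeded at
θ_acc[0]) is smooth but drifts. They are blended per sample as

    θ_hip = α·θ_gyro + (1−α)·θ_acc,  α = 0.99,

after which the residual drift is removed as a least-squares linear
trend and the result is smoothed with second-order loess (local
quadratic regression, tricube weights). Applying the blend to the
whole-trial integral and detrending afterwards is the literal pipeline
order; a per-sample recursive complementary filter
(`recursive_filter: true`) is provided for comparison and gives
equivalent results on simulated gait.

Foot pitch channels are conditioned with a robust median outlier rule —
a sample is an outlier iff |x − median| > threshold × 1.4826 × MAD
(strict inequality, so a constant series has no outliers; 1.4826 makes
the MAD consistent with a Gaussian SD) — with flagged samples linearly
interpolated, then a centered 11-sample moving average.

**A consequence worth knowing:** a global median rule with threshold 1–2
scaled MADs treats any excursion occupying less than half the samples as
deviation. The swing-phase foot-pitch excursion occupies ~40 % of each
stride, so at the default threshold it is flattened toward the stance
dwell level. Downstream, the rectified foot-pitch integral (PC2)
therefore measures mostly the stance/slope contribution rather than the
swing bump. Class separability does not depend on the bump (see the
feature geometry below), but users who want the swing excursion
preserved should raise `outlier_threshold` well above the default.

### 2. Stride segmentation and features

A hip cross-point (HCP) is an instant where the left and right hip-angle
curves cross. Crossings are found by sign changes of the difference,
interpolated to the nearest sample, and debounced: consecutive HCPs
closer than 0.3 × the nominal step period (60/BPM s) are merged, which
suppresses noise-induced double crossings without rejecting true events
at any studied cadence. Consecutive HCP pairs delimit the half-open
segments on which features are computed; partial cycles at the trial
edges are discarded.

Per segment:

* **PC1** (deg) = max hip flexion across both sides minus the *opposite*
  hip's angle at that same instant. The opposite hip is read at the peak
  instant (not at its own extremum) because the quantity is a single
  inter-hip amplitude. PC1 is invariant to a common constant shift of
  both hip channels.
* **PC2** (deg·s) = trapezoidal integral over the segment of
  max(θ_foot, 0), summed over both feet. Always ≥ 0.
* **PC3** (deg) = the common foot pitch where the two foot-pitch curves
  are closest, searched in the central 20–80 % of the segment as a
  single-support proxy; the mean of the two feet at the minimizing
  instant is returned. If even the closest approach exceeds 10° (both
  config-exposed), PC3 is missing (NaN). On ramps PC3 reads the ground
  slope (±5.9°), on level ground ≈ 0.

Features are labeled by terrain, filtered per class with the same
scaled-MAD rule at factor 2 (a vector is dropped if any finite dimension
violates; a class that would fall below two vectors is kept unfiltered),
and z-scored per classifier layer using training statistics only.
Z-scoring was chosen for the otherwise unspecified scaling stage because
PC2's units (deg·s) would otherwise be dwarfed in the mixture geometry.

### 3. Gaussian mixture classifier (EM, from scratch)

Each classifier layer is a K = 3 component Gaussian mixture
f(x) = Σ c_k N(x | μ_k, Σ_k), fit by EM:

* E-step: responsibilities γ_nk = c_k N_k(x_n) / Σ_j c_j N_j(x_n),
  computed in log-space with the log-sum-exp trick;
* M-step: weighted sample moments
  μ_k = Σ γ x / Σ γ, Σ_k = Σ γ (x−μ)(x−μ)ᵀ / Σ γ + ridge·I,
  c_k = (1/N) Σ γ, with ridge = 1e-6 keeping covariances positive
  definite;
* densities evaluated via Cholesky factorization (no explicit inverses);
* stop when the relative log-likelihood change < 1e-6 or after 200
  iterations. The log-likelihood trace is non-decreasing (EM guarantee),
  and tests verify it to within 1e-8 on random data.

Initial weights are uniform (1/3 each). Means and covariances are
initialized from labeled class statistics ("supervised init"), which
fixes EM's identifiability; a label-blind alternative (`init: random`,
K data points as means, pooled covariance) exists, after which
components are mapped to classes by majority vote of training-point
posteriors. The vote must produce a bijection; a tie or a captured-empty
component raises an error advising re-initialization — on this package's
benchmark data the blind path usually fails that vote precisely because
the merged level/ramp class is multi-modal, which is why supervised init
is the default. Classification is the Bayes rule argmax_k γ_k(x), ties
toward the smaller index.

### 4. Two-layer strategy and evaluation

Layer 1 operates on scaled (PC1, PC2) with labels collapsed to
{LW∪RA∪RD = 1, SA = 2, SD = 3}; stairs are geometrically distinctive
there (SA demands much larger hip flexion; SD much smaller). Strides
routed to the merged class are passed to layer 2 on scaled (PC1, PC3),
where the ground slope separates LW/RA/RD. Layer 2 trains on true
LW/RA/RD strides only (not on layer-1 survivors), keeping the two
recognizers independently trained.

Evaluation is leave-one-out cross-validation: N strides → N folds, each
fold refits the outlier filter, scalers and both mixtures on the
remaining N−1 strides and predicts the held-out stride. Layer-1 accuracy
(trace of the 3×3 confusion matrix / total × 100) is scored over all
folds; layer-2 accuracy is conditioned on strides whose true mode is
level/ramp *and* which layer 1 routed correctly, so routing errors count
against layer 1 only. Whether the original two-stage evaluation included
misrouted strides in its second stage is not defined; this package's
conditioning choice is stated here rather than asserted as universal.

## Synthetic gait simulator

No public dataset accompanies this problem setting, so the package
ships a seeded parametric simulator that emits mutually consistent
channels with known ground truth:

* hips: antiphase raised-cosine waves, left = offset + A·cos(2πt/T);
* feet: ground-slope baseline + raised-cosine swing excursion occupying
  40 % of the stride starting at phase 0.55 (legs half a stride apart),
  so double-support windows dwell at the slope;
* accelerometer g_x = 9.81·cos θ, g_y = 9.81·sin θ (tilt inverts
  exactly at zero noise), gyroscope = analytic dθ/dt + bias drift,
  noise added per channel.

Default terrain profiles (degrees): LW A=20 offset 5, swing 15, slope 0;
SA A=20+15.5 (half the 31° stair-nosing incline from a 0.3 m × 0.18 m
step) offset 10, swing 20; SD A=12 offset 0, swing −25 (toe-down);
RA/RD as LW but slope ±5.9° (standard wheelchair-ramp grade) and offsets
7/3. Default noise: accel 0.3 m/s², gyro 1 deg/s, bias drift
0.5 deg/s per minute, foot 0.5° — strong enough that raw channels are
visibly noisy, while the conditioned features remain well separated.

What the simulator does *not* emulate: inter-subject variability,
stride-to-stride cadence jitter, soft-tissue artifact, non-sagittal
motion, transition strides between terrains, and foot-strike impact
transients. Passing tests therefore demonstrate the pipeline's internal
correctness and its behavior under the stated noise model, not clinical
performance; the original four-subject recordings are not publicly
available, so published subject-level accuracies are not reproduced
here.

## Numerical and design choices

* **loess span 0.02** (fraction of series length, window forced odd and
  ≥ 5). The window scales with trial length, so large spans over-smooth
  long trials: at 0.05 a 40-stride trial's window is ~2 stride periods
  and visibly clips the hip-angle peaks. At 0.02 peak attenuation is ~4 %
  on 40-stride trials (a known limitation — PC1 sits slightly below its
  2A expectation, consistently within a dataset) and negligible on short
  trials.
* movmean window 11 samples (~0.11 s at 100 Hz): short enough to leave
  the stance dwell untouched.
* MAD scale fixed at 1.4826; strict ">" so MAD = 0 flags nothing.
* Outlier replacement: linear interpolation; edge outliers take the
  nearest valid value.
* PC2 integrates samples [HCP1, HCP2] inclusive so a nominal 1-second
  segment integrates exactly one second.
* EM: tol 1e-6 relative, max_iter 200, ridge 1e-6 — all config-exposed.
* Degenerate inputs raise typed errors rather than coercing: zero
  gravity vectors, all-outlier series, empty mixture components,
  non-SPD covariances (also re-checked before model serialization),
  missing terrains at training time, missing PC3 on a merged-class
  stride at prediction time.
* Determinism: the simulator derives per-trial substreams from one seed;
  training with supervised init and LOOCV contain no randomness, so
  reports are bit-reproducible.

## Problem sizes used in validation

The shipped benchmark simulates 5 terrains × 40 strides (≈ 79 HCP
segments per terrain, N = 395 feature vectors) at each of BPM 90/110/130
and runs full LOOCV per cadence; EM properties are checked on 100 random
datasets (N = 300, d = 2, K = 3) and a 900-point three-cluster recovery
problem. These sizes were chosen to exercise every code path at
comfortably interactive runtimes.
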