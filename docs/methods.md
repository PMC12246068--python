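# Methods

`tremorkit` detects and quantifies Parkinson's disease (PD) rest tremor from
a single wrist-worn tri-axial gyroscope, from raw angular-velocity streams
to weekly aggregated tremor measures. This note documents the model, its
assumptions, the tunable parameters, the synthetic-data generator the test
suite relies on, and the numerical choices that were genuinely open.

## Signal model and analysis unit

Recordings are angular-velocity streams in deg/s with absolute local
timestamps, possibly with gaps (non-wear, charging). They are split into
contiguous blocks wherever the inter-sample interval exceeds 1.5x the
nominal interval (the factor tolerates timestamp jitter without
fragmenting), resampled to whichever canonical rate of {50, 100} Hz is
closer to the inferred rate (anti-aliased polyphase resampling; ties prefer
100 Hz; rates below 50 Hz are refused), and cut into consecutive,
non-overlapping 4-s windows that never span a gap. Windows are
non-overlapping because the weekly measures count windows as units of time;
overlapping windows would double-count.

PD rest tremor is a 3-7 Hz oscillation of the relaxed limb, roughly
uniaxial at the wrist, waxing and waning over seconds to minutes, often
with a visible second harmonic. The detector's job is to recognise this
pattern per window against confusers whose harmonics also reach 3-7 Hz
(gait arm swing, cycling, tooth-brushing-like rhythmic activity).

## Per-window features

Per window we compute a Welch PSD per axis (2-s Hann segments, 50% overlap,
constant detrend, one-sided density) and sum across the three axes, making
the spectrum invariant to how the tremor axis projects onto the sensor
frame. The 2-s segment length is a bias/variance compromise: 0.5 Hz
resolution localises 3-7 Hz peaks while still averaging three segments per
window.

From the summed PSD we extract:

* **Peak frequency** over 0.5-25 Hz (DC and drift excluded; ties resolve to
  the lowest frequency; an all-zero PSD yields null, treated as non-tremor).
* **12 MFCCs** from a 15-filter triangular filterbank spanning 0-25 Hz.
  Filter edges are obtained by inverse-warping 17 equally spaced points of
  a concave warp `w(f) = ln(1 + f/4 Hz)`, which places denser filters over
  the tremor band; the warp is pluggable (a `linear` preset exists) so an
  alternative inertial mel curve can be dropped in. Coefficients are the
  orthonormal DCT-II of log filterbank energies, orders 1..12; order 0
  carries the overall log energy and is discarded, which makes the
  remaining coefficients exactly invariant to signal gain. This scale
  invariance is the property that lets a detector trained on one device
  transfer to another with different gain and drift; the log-energy floor
  is 1e-30, far below any physical energy, because a larger floor (~1e-12)
  already perturbs coefficients of attenuated signals at the 1e-9 level.
* **0.5-3 Hz band power** (trapezoidal integral), the signature of slow
  voluntary arm movement, above drift and below tremor.
* **Tremor power** `log10(P_T + 1)`, where `P_T` integrates the PSD over a
  1.25 Hz-wide band centred on the dominant 3-7 Hz peak ("1.25 Hz" names
  the full width; the band is not clipped at the 3/7 Hz borders). The log
  matches the known log-linear relation between clinical ratings and tremor
  angular velocity; the +1 pins zero power to zero log-power. `P_T` uses a
  rectangle (bin-sum) integral over bins whose centres fall in the band: on
  the 0.5 Hz grid this captures the full 3-bin main lobe of a Hann-windowed
  tone, so a tone of amplitude A recovers `A^2/2` almost exactly, whereas an
  edge-interpolated trapezoid undercuts the peak by ~9%.

## Detection cascade

A binary logistic regression on the z-scored MFCCs (standardisation
constants from the training pool; a mild L2 penalty, default strength 0.01
on standardised features, keeps coefficients finite without material bias)
produces `p_tremor`. Three asymmetries push the operating point towards
specificity, the priority for continuous monitoring where non-tremor time
dominates:

1. **Calibrated threshold.** tau is the smallest value such that at least
   95% of non-tremor training windows fall strictly below it (a window is
   positive when `p >= tau`), so training specificity lands in
   [0.95, 0.95 + 1/n).
2. **Clinical criterion.** The window's peak frequency must lie inside
   3-7 Hz (inclusive at both ends); otherwise the window is non-tremor.
3. **Arm-movement rejection.** Windows whose 0.5-3 Hz power exceeds
   theta_move are rejected outright: slow-movement harmonics both trigger
   false positives and corrupt the tremor-power estimate. theta_move is
   10^(midpoint of the two cluster centres) of a two-cluster K-means
   (k-means++, fixed seed, 10 restarts) on log10 band power across all
   training windows, exploiting the bimodality of the band-power
   distribution (quiescent wrist vs voluntary movement).

During training, cycling windows carry sample weight 100 (likelihood-
equivalent to replication but cheaper) to penalise the cycling-as-tremor
failure mode. The movement flag is computed for every window regardless of
the classifier outcome because rejected windows define "inactive time", the
denominator of tremor time. By construction the cascade can only shrink
the tremor-positive set relative to the classifier alone; a
`movement_filter=False` ablation reproduces the pipeline without step 3.

The classifier decision and the clinical criterion are gain-invariant;
the movement flag deliberately is not (theta_move is an absolute power).
Models are persisted as JSON together with a hash of the full configuration
and refuse to score features produced under a different configuration.

Cross-subject generalisation requires the tremulous training subjects to
span the 3-7 Hz band: the cepstral envelope encodes where the peak sits, so
a classifier trained on one or two tremor frequencies does not recognise
tremor at unseen frequencies (visible when training on tiny cohorts).

## Weekly measures

Window decisions aggregate per subject over consecutive 7-calendar-day
blocks anchored at the first day with data (a simple, reproducible
anchoring; any other anchor would do). Only daytime windows (start time in
[08:00, 22:00) local) on valid days count. A day is valid with >= 10 h of
recorded data over the whole day (wear-time compliance, not daytime only);
a week is valid with >= 3 valid days. Daily wear is derived from window
counts (4 s x windows), identical to non-gap recorded time up to the
sub-4-s trailing remainder of each block.

* **Tremor time**: detected tremor windows as a percentage of inactive
  windows (those not rejected as arm movement).
* **Tremor power**: median, mode and 90th percentile of the per-window log
  tremor power over detected tremor windows. The mode is the argmax of a
  Gaussian KDE (Silverman bandwidth) on a 512-point grid spanning the
  observed range ("the peak of the probability density" names no
  estimator; a histogram-mode fallback is exposed). Percentiles use linear
  interpolation between order statistics.

Power measures are reported only for valid weeks whose tremor time reaches
the false-positive gate (default 3.5%, re-derivable on a new cohort as the
90th percentile of control tremor time via `control_gate_from_cohort`);
below the gate most "tremor" windows are likely false positives and a power
summary would describe noise. The gate comparison is inclusive (>=) and
configurable. Lowering the gate can only add powered subject-weeks.

## Evaluation

**LOSO-CV.** Each fold retrains everything (classifier, tau, theta_move) on
the training subjects only and scores the held-out subject; tau calibration
uses only that fold's training negatives (no leakage). Sensitivity counts a
tremor-labelled window as hit only when the final state is tremor (a
rejected tremor window is a miss). Filtered specificity excludes rejected
windows from its denominator — they are excluded from monitoring time — and
a secondary unfiltered specificity (classifier + clinical criterion over
all non-tremor windows) quantifies what the movement filter buys. Confusion
counts cover all labelled windows so they sum to the fold size. Per-
activity specificities feed a prevalence-weighted specificity (weights =
pooled activity prevalence over all subjects' non-tremor windows,
renormalised over activities the subject performed; equal weights
available), which compares subjects fairly when their activity mixes
differ. Summary statistics are means and population SDs over folds with
defined metrics; folds whose subject lacks tremor labels report null
sensitivity and are excluded from the sensitivity mean.

**Test-retest reliability.** Weekly measures from two consecutive weeks are
compared with the two-way, absolute-agreement, single-measurement
intraclass correlation ICC(A,1) — chosen because the two weeks are fixed
"raters" and a constant week-to-week shift should be penalised — with the
F-method 95% CI. The estimate is computed via pingouin and cross-checked in
the test suite against an independent ANOVA mean-squares implementation.
The variant is configurable.

## Synthetic cohort generator

The generator emulates the statistical structure the detector assumes, with
exact ground truth, so the whole pipeline is testable without patient data.
Per subject and day, fixed-length 60-s activity bouts are drawn from
per-hour probabilities over {rest, voluntary movement, gait, cycling}
(nights are ~97% rest; daytime is 55/30/10/5%, matching the roughly half-
active daytime seen in wrist-wearable compliance data). Signal components:

* **Tremor** (tremulous subjects only, during rest runs): Poisson episodes
  (default 6/h of rest time), lognormal duration (median 60 s, log-SD 0.7)
  and peak amplitude (median 20 deg/s, log-SD 0.75 — the range of mild to
  moderate wrist tremor), per-subject frequency uniform in 3.5-6.5 Hz,
  second harmonic at 0.25 relative amplitude, raised-cosine 2-s on/off
  ramps, +-20% sinusoidal amplitude modulation at 0.1-0.3 Hz, projected on
  a random per-episode fixed axis.
* **Voluntary movement**: band-limited (0.5-3 Hz Butterworth-filtered)
  Gaussian process at 25 deg/s RMS.
* **Gait**: 0.9-1.1 Hz arm-swing fundamental with harmonics 2f-5f decaying
  by 0.4 per order, 40 deg/s.
* **Cycling**: 0.8-1.5 Hz with slowly decaying harmonics (0.55 per order,
  15 deg/s) that deliberately land in 3-7 Hz — the hard confuser.
* **Noise and drift** everywhere: white noise (1 deg/s per axis) and slow
  baseline wander (1.5 deg/s below 0.3 Hz, synthesised at 2 Hz and
  interpolated).

One non-wear gap per day (default 1 h, emulating charging) is placed
uniformly at random with boundaries snapped to the 4-s window grid, so
generated windows, written CSV fixtures and re-read recordings agree on
window starts. Timestamps are naive local time from 00:00 of day 1, so
daytime filtering is exercised. Ground truth per window: tremor when the
sample-level tremor mask covers >= 50% of the window, the most prevalent
activity class, and the true frequency/mean envelope amplitude of tremor
windows. A single seed drives everything; identical configs are
bit-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: annotation noise and missed subtle tremor,
re-emergent vs rest tremor distinctions, fine motor activities
(tooth-brushing, stirring) whose spectra genuinely mimic tremor, amplitude
distributions of real PD cohorts, postural transitions, and
device-specific noise floors. The synthetic task is easier than real life;
detection floors passed here (specificity >= 0.95, sensitivity >= 0.8) are
consistency checks of the pipeline against its own calibration target, not
predictions of clinical performance.

## Problem sizes and determinism

Default test and acceptance runs use a 20-subject cohort (10 tremulous,
2 simulated days each at 100 Hz, ~828k windows) for LOSO, a 4-subject
7-day cohort at 50 Hz for the weekly measures, and window-level synthetic
sets for classifier experiments — sizes chosen so a full run completes in
minutes on one core while every code path (multi-day validity, gaps,
daytime filtering, all activity classes) is exercised. All randomness
flows from explicit seeds; training, clustering and simulation are
bit-reproducible given seed and config.

## Known limitations

* The inertial mel warp uses a generic `ln(1 + f/4)` curve; the exact
  published warp for inertial signals can be supplied via `warp_funcs`.
* theta_move is a single absolute power threshold; devices with very
  different noise floors may need refitting (the fit is one function call).
* Weekly blocks are anchored per subject at the first recorded day;
  calendar-week anchoring would shift week boundaries.
* The ICC's F-method CI assumes normal weekly measures; heavy-tailed
  tremor-time distributions make the CI approximate.
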