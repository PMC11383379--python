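# Methods

This note documents the models, parameters and numerical choices behind
`cocostep`, in the spirit of a methods appendix: what is computed, what
the synthetic data emulate, and where genuinely open design choices were
resolved.

## Task and protocol model

The task is recumbent stepping on a one-degree-of-freedom device: the
contralateral arm and leg extend together, so a single angle describes
the whole configuration. A *stride* runs from one extension onset of the
perturbed leg to the next and contains two *steps*: the perturbed step
(extension of the perturbed leg) and the recovery step (extension of the
contralateral leg). Pacing is 60 steps/min, so the nominal stride lasts
2 s.

`ProtocolConfig` encodes one 10-minute task: 120 s unperturbed (pre),
360 s perturbed, 120 s unperturbed (post); a 200-ms resistance
perturbation per perturbed stride, triggered at the perturbed leg's
extension onset or midextension (the 50%-range crossing of the extension
half-cycle, a quarter stride into a sinusoidal profile); and one random
catch stride — perturbation withheld — in every five perturbed strides.
The catch scheme places exactly one catch at a seeded-random position
inside each consecutive window of five perturbed strides (trailing
partial windows carry none), which makes the 1-in-5 ratio exact and the
catch count equal to `floor(n_perturbed / 5)`.

## Synthetic kinematics

The stepper angle rises during left-limb extension over a default 0–60°
range. Each scheduled stride is rendered as one full cycle of the
sinusoidal profile over its own duration; durations are the 2-s nominal
plus Gaussian jitter of SD `temporal_error_scale` (default 50 ms,
clipped to ±50% of nominal). Because each stride is a complete cycle of
the same shape, the time-normalized profile of every unperturbed stride
is exactly the baseline curve: temporal and spatial errors are
independently controllable.

The device's true kinematic response to a resistance pulse is not
specified anywhere, so the injected deviation is a free generator
choice: a smooth `A·sin²(π·(t−t₀)/W)` bump of amplitude
`A = spatial_error_scale` (young default 12°, older 8°) starting at the
perturbation command time, with
`W = perturbation_duration + perturbation_decay` (0.2 s + 0.5 s
default). The bump points along the perturbed leg's extension direction
and its support stays inside the stride, which keeps the stride-boundary
turning points — and therefore stride counts and durations — exact.
Consequences worth knowing:

- extension-onset bumps start at a turning point; the 6-Hz detection
  smoothing shifts that onset by up to ~10 ms (within the 20-ms event
  tolerance);
- midextension bumps end near the contralateral turning point and drag
  it earlier by up to ~100 ms on perturbed strides. This is physically
  plausible (the resisted leg genuinely lags) but means contralateral
  event accuracy is only guaranteed on unperturbed strides; the spatial
  error metric is unaffected because it uses stride boundaries only.

A quarter-stride lead-in and tail are prepended/appended so the first
and last extension onsets are interior extrema; real recordings likewise
start before and end after the paced stepping.

## Synthetic EMG

Each of the 12 channels (tibialis anterior, soleus, rectus femoris,
semitendinosus, anterior/posterior deltoid × left/right) is band-limited
(30–200 Hz) Gaussian noise amplitude-modulated by a smooth per-step gain:
within each step the active muscle bursts with a `sin²` profile that
vanishes at the step boundaries (so envelope leakage across the 20-Hz
low-pass is negligible), scaled per muscle and step phase. The rectified
mean of the carrier is proportional to the gain, so the ratio of two
channels' envelope integrals over a step equals the ratio of their burst
amplitudes — which is what makes CCI targets exactly plantable.

**Normalization couples the two phases of a pair.** CCI is computed from
envelopes normalized by each channel's own grand mean. Writing
`r = c/(2−c)` for the raw integral ratio a target CCI `c` demands, the
per-phase amplitude shares of the two muscles must solve a 2×2 system
(`solve_pair_amplitudes`). The system forces, for a pair whose agonist
alternates between phases, both phase ratios onto the *same* side of 1,
and for the one pair whose agonist is the same muscle in both phases
(the left deltoid pair in the published role table) the two ratios must
*straddle* 1. Targets violating this — e.g. `c₁ + c₂ = 2` with
`c₁ ≠ 1` — are rejected with an explanatory error rather than silently
approximated. This is a mathematical property of grand-mean
normalization applied to a single task with statistically stationary
strides, not a generator shortcut; with several tasks pooled (roles swap
between left- and right-side tasks) or block-varying activity, real data
have more degrees of freedom. Default profiles therefore assign
driving/resisting status per pair (both phases alike), the left deltoid
pair stays neutral, and `n_driving_pairs` realizes odd requests at the
nearest even count.

Stride-to-stride amplitude variability is multiplicative Gaussian jitter
of SD `envelope_noise_sd` (default 0.2, a realistic ~20% burst-amplitude
variation) per muscle, stride and phase. Group profiles: *young* — five
pairs driving (CCI 0.6, 10/12 entries), deltoid pair neutral; *older* —
shank pairs driving (CCI 0.7, 4/12), two pairs resisting (CCI 1.3), rest
neutral, smaller error scales.

What the generator does **not** emulate: EMG nonstationarity and fatigue
drift, electrode cross-talk, motion artifacts, within-block strategy
changes (targets are constant over the task), force/torque dynamics of
the device, and between-subject heterogeneity beyond the seeded noise.
Passing recovery tests therefore demonstrates correctness of the
processing chain, not robustness to every pathology of real recordings.

## Stride segmentation

Extension onsets are turning points of the angle, detected on a
zero-phase 6-Hz 4th-order Butterworth-smoothed copy: minima for the left
leg, maxima for the right. Extremum candidates need a prominence of 25%
of the angular range and a separation of half a nominal stride from
same-type neighbours, which rejects perturbation-induced wiggles. Event
times are refined to sub-sample precision by parabolic interpolation
(the 10-ms grid is coarse against 50-ms effects); on noiseless traces
events land within microseconds of ground truth. Strides are classified
into blocks by their midpoint (onsets can jitter by a few ms around a
block boundary, midpoints cannot). Perturbation events come from the
logged command times (device log or generator); perturbed-block strides
without a command become catch strides; pre/post/catch strides receive a
virtual perturbation event at the mean latency of the task's real
events; strides missing any of the four events are excluded (with a
count).

## Motor errors

Temporal error is the signed stride duration minus `2·(60/pacing_rate)`
seconds. The baseline profile averages the pre-block strides' angle
resampled to 101 points on normalized time (percent-of-stride
convention), excluding the first 5 pre strides as ramp-up
(configurable). Spatial error is the maximum *absolute* pointwise
deviation of a stride's 101-point profile from the baseline — absolute
rather than signed, matching a nonnegative error axis — and is invariant
to stride duration by construction.

## Envelope chain and CCI

Envelope chain order: resample to 1 kHz (polyphase, rational
approximation of the measured rate) → 30–200 Hz band-pass → full-wave
rectify → 20 Hz low-pass, every filter a 6th-order Butterworth design
applied forward–backward. Zero-phase filtering was chosen because the
analysis is offline and a causal 20-Hz filter's group delay would smear
event-locked integrals at the 200-ms perturbation scale; the cost is a
doubled effective attenuation (and a few percent of passband droop
inside the band — a 100-Hz unit sine envelopes to ~0.97·2/π). Envelopes
are clipped at zero (filtfilt undershoot) and normalized per channel by
the grand mean pooled over all of a subject's tasks, never by maximal
voluntary contraction.

CCI integrals are trapezoidal in real time over the step windows
(onset→contra-onset, contra-onset→end) with interpolated edges — real
time keeps the `I` values interpretable; the ratio is unaffected.
A pair is *inactive* (CCI = NaN) when `I_ag + I_ant` falls below 5% of
what two grand-mean-level envelopes would integrate to over the step;
this separates "controls the motion" from "not active", which CCI ≈ 1
alone cannot. Epoched, event-anchored envelopes use a 25/25/50-sample
grid (plus endpoint) across the three inter-event segments, proportional
to typical segment durations; a zero-length first segment (extension
onset tasks trigger at zero latency) fills with the boundary value.

Classification uses the per-bin point estimate — driving below 1,
resisting above — with an optional significance mask from the cluster
test; the resistance ratio counts resisting entries out of 12 per bin
from point estimates, since per-subject per-minute ratios vary while
significance is a group-level statement. Note that for a neutral pair
the point estimate sits at 1, so envelope noise classifies it as
resisting in roughly half the bins; the ratio is best read as a relative
measure between groups.

## Time-course statistics

Per-stride samples are smoothed per subject with a Gaussian kernel onto
a shared grid (default one point per minute, bandwidth equal to the grid
spacing — resolution-matched smoothing; 10 points/min with a 6-s
bandwidth for error time courses). Each subject contributes one curve
plus a kernel-mass weight per grid point, and subjects weigh equally in
group statistics, so stride-count differences cannot bias the group
curve.

The one-sample test against CCI = 1 computes pointwise weighted
t-statistics (reliability-weighted variance, effective
`n = 1/Σu²`, reducing to the classic t under equal weights), forms
clusters as maximal same-sign runs exceeding the pointwise two-sided
α = 0.05 t-threshold (df = subjects − 1), and scores each cluster by its
summed |t|. The null distribution of the maximum cluster mass comes from
sign-flipping each subject's deviation from the null value (seeded;
default 1000 resamples, mandatory seed), with
`p = (1 + #{null ≥ mass}) / (1 + n_boot)`. The sign-flip second moment
is flip-invariant, so the bootstrap is fully vectorized. Simulated
family-wise error over 500 null replicates of 10 subjects sits near the
nominal 0.05 (the test suite asserts 0.02–0.08). With very strong
effects the attainable p is floored by near-complete flip patterns
reproducing the observed mass — an inherent property of sign-flip nulls
at small n.

Block-endpoint tables (first/last defined grid value per block per
subject) are emitted for downstream repeated-measures ANOVA in any
standard statistics package; the rANOVA itself is deliberately not
reimplemented. Group comparisons use a two-sample Student t-test after
per-group 1.5×IQR Tukey-fence outlier rejection (the rule is
configurable; at least 3 subjects per group must survive).

## Problem sizes and defaults

Validation runs use the full 10-minute protocol at its stated rates
(100 Hz kinematics, 1.1 kHz EMG). Parameter-recovery suites use
10-subject cohorts with CCI targets {0.3, 1.0, 1.7} — recovered within
±0.005 noiseless and well within ±0.15 at default noise — and a
15° injected deviation recovered within 10%. The demonstration cohort is
6 young + 4 older subjects, sized for a laptop-scale run while keeping
both groups above the outlier-rejection minimum.

## Known limitations

- Single-task normalization restricts the representable per-pair CCI
  target combinations (see above); multi-task simulation would lift this
  but is not implemented.
- Contralateral-onset detection degrades to ~100 ms on perturbed
  midextension strides (lagging turning point); step-level integrals on
  those strides shift accordingly, though the CCI ratio is largely
  insensitive because both channels shift together.
- The cluster test covers the one-sample case against a reference value
  only; paired or two-sample cluster tests are out of scope.
- `SubjectProfile` targets are constant over a task: adaptation dynamics
  (drifting CCI, error washout curves) are not part of the generative
  model, although the analysis side would quantify them if present.
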