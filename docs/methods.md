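# Methods

`fmca` scores upper-extremity motor function on a continuous 0–1 scale from
marker-less skeleton tracking, for three representative Fugl–Meyer
assessment (FMA) items: elbow extension during hand-to-knee (T1), shoulder
abduction 0–90° (T2), and shoulder adduction/inward rotation during
hand-to-knee (T3). This note records the model, its assumptions, the
defaults that matter, and what the synthetic data do and do not show.

## Kinematic features

A trial is a 30 Hz sequence of 3-D landmark positions (Kinect V2 joint
vocabulary, meters, any consistent right-handed sensor frame). Channels are
low-pass filtered with a third-order Butterworth at 10 Hz, applied
forward–backward (zero phase) with odd-symmetric edge extension of length
3 × order. Zero-phase filtering is chosen so that phase segmentation is not
biased by filter lag; the effective magnitude response is the squared
Butterworth response.

Joint angles are computed from landmark geometry only, so every feature is
invariant to rigid motion of the sensor frame:

- **elbow flexion** — 180° minus the interior shoulder–elbow–wrist angle
  (0° = fully extended);
- **shoulder abduction** — angle between the upper-arm vector and the trunk
  axis (spine-shoulder → spine-mid);
- **shoulder flexion** — elevation of the upper arm within the sagittal
  plane, built from the trunk axis and the inter-shoulder (frontal) axis;
- **shoulder internal rotation / forearm pronation** — signed rotation of
  the distal segment about the proximal segment axis, read against the
  body-forward axis projected onto the rotation plane. The forward axis is
  used as the reference (rather than the trunk axis) because it stays
  nearly perpendicular to both rotation axes throughout these movements;
  a near-parallel reference would amplify landmark noise by roughly
  1/sin(axis–reference angle). Samples whose projection degenerates are
  flagged undefined and excluded; a window with more than 50% undefined
  samples is an error.

**Phase segmentation.** Each trial is split into an *onset* (pre-movement
baseline) and a *motion* window using the test's primary angle: the
baseline is the mean over the initial 10% of samples, and motion begins
when the angle departs the baseline by more than 5% of its total excursion,
with an absolute floor of 2° so jitter cannot trigger a departure; motion
ends at peak excursion. A flat trajectory (excursion under the floor) falls
back to a full-trial motion window with a warning. These thresholds are
configurable (`rest_fraction`, `threshold_fraction`); the specific rule is
this package's own deterministic choice for a step that different capture
systems implement differently.

**Features per test** (all in degrees): T1 uses the elbow-angle range of
motion; T2 uses the shoulder-abduction ROM plus nine posture-maintenance
features (means and SDs of abduction, elbow flexion, shoulder flexion and
pronation over the onset or motion window); T3 uses the abduction and
inward-rotation ROMs. ROM is measured as the range from trial start through
the peak, i.e. peak excursion relative to the resting baseline — the
sub-threshold part of the rise belongs to the movement, and clipping it at
the departure threshold would systematically understate the range by the
threshold amount. Mean-type maintenance features are re-expressed as
absolute deviations from the configured desired posture angle, so a single
"smaller is better" membership orientation covers all maintenance features;
SD features are raw sample standard deviations.

## Fuzzy scoring model

Scoring is Mamdani inference. Each feature `x` is fuzzified on a universe
[0, β], where β is the desired feature value of the instructed motion
(or 30 for SD features). Input sets are triangular/ramp shaped:
"performed fully" rises linearly 0→1 over [0, β]; "performed partially"
peaks at β/2; "not performed" is the exact pointwise complement of
"performed fully". Two-level features reuse the ramp pair; maintenance
inputs are deviations, so "maintained" is the falling ramp. Inputs are
clamped to the universe — a patient exceeding the desired ROM saturates at
full membership rather than erroring.

Rule antecedents combine atoms with min (AND) / max (OR); firing truncates
the consequent output set; rule weights are fixed at 1. The output universe
is [0, 1] with three triangular sets peaking at 0, 0.5 and 1 (FM score
0/1/2). One T2 rule has a negated consequent ("FM score is NOT high"); it
implicates onto the pointwise complement of the high set by default, with
an implicate-onto-the-union alternative behind the `negated_mode` config
switch. Truncated sets are aggregated pointwise by max and defuzzified by
centroid (trapezoidal integration on a 2001-point grid; doubling the grid
changes the result by < 1e-4). The raw centroid lives in [1/6, 5/6] — the
centroids when only the lowest or only the highest set fires fully — and is
rescaled linearly so those anchors map to 0 and 1. Analytic anchors are
used rather than empirical per-cohort minima/maxima so the scale is stable
across data sets.

One structural consequence worth knowing: the T3 rulebase contains
"either feature not performed → medium", which under max-aggregation fires
fully when *both* features are zero; the continuous T3 score therefore has
an analytic floor of 0.375 rather than 0 for a patient with no movement.
T1 and T2 reach 0 exactly.

A crisp three-point counterpart (`FM_3A`) binarizes every atom membership
at τ = 0.5 and evaluates the same rules as Boolean logic with a fixed
precedence: any fired hard-fail (lowest-set) rule forces 0; otherwise a
fired high rule gives 2, a fired medium rule gives 1; a fired negated-high
rule caps the result at 1. This precedence is the only order consistent
with all three rulebases' consequents; a side effect is that T1's crisp
score jumps 0→2 at β/2 (its "partial" region is absorbed by the binarized
"not performed" set), which is why the continuous scale exists.

The extended seven-point clinician scale maps to integers as 0→0, 0+→1,
1−→2, 1→3, 1+→4, 2−→5, 2→6; the upper five values are the published sum
conversion and the two lowest are its natural completion.

### Defaults

| parameter | default | why |
|---|---|---|
| β, T1 elbow-extension ROM | 60° | declared default for the instructed reach |
| β, T2 abduction ROM | 90° | the instructed 0–90° abduction |
| β, T3 abduction / inward-rotation ROM | 40° / 30° | declared defaults for hand-to-knee |
| β, maintenance deviations | 30° | tolerance before "not maintained" saturates |
| β, SD features | 30 | published bound for SD-type inputs |
| desired posture angles | 0° each | instructed start/maintenance postures |
| τ (crisp threshold) | 0.5 | midpoint of the membership range |
| output grid | 2001 points | < 1e-4 discretization error |

Only the T2 ROM target and the SD bound are anchored in the published
system; the remaining β values are package defaults, kept in the scoring
config (`fmca dump-config`) so a deployment can substitute clinic-specific
targets without code changes.

## Worst-case error propagation

The achievable number of distinguishable grades is limited by sensor error.
The chain has three stages.

1. *Landmark error → angle error.* For a three-point angle, each endpoint
   error (mean + 1 SD of the published tracking error, in cm) is treated as
   a lateral displacement of its segment: a segment of length L with
   endpoint errors e₁, e₂ can tilt by up to arcsin((e₁+e₂)/L), and the two
   segment tilts add. Angles whose error was measured directly (shoulder
   internal rotation, 16°) pass through unchanged. This closed form is this
   package's declared model; the published per-feature error table is
   shipped alongside as a fixture because its derivation was not printed,
   and the two are never conflated.
2. *Angle error → score error.* The feature space is swept (exhaustively
   for one or two features, 61 points per axis for two, seeded uniform
   samples for ten) and at each nominal vector the score is re-evaluated
   under every ± sign combination of the per-feature errors (exhaustive up
   to four features, 64 seeded sign vectors otherwise), clamped to the
   universe; the maximum absolute score change is the worst case.
3. *Score error → grades:* ⌊1 / max error⌋ disjoint intervals fit in [0, 1].

Applied to the published error column this arithmetic reproduces the
published grade counts (9/7/12). Applied to the package's own stage-1 model
under the shipped β values, the worst-case score errors are far larger
(≈ 0.37–0.47, i.e. 2 grades): summed mean+SD endpoint errors on short arm
segments are a deliberately pessimistic bound, and the shipped β values
compress the universes. Both routes are reported side by side by the
acceptance script.

## Synthetic data

The generator drives a shoulder–elbow–wrist–hand chain on a fixed torso
with minimum-jerk joint-angle profiles: 1 s resting baseline, a rise to
`ability` × β on the test's commanded channels over ≈ 4 s, then a hold.
Segment lengths follow the published reference anthropometry (upper arm
27.2 cm, forearm 29.4 cm, torso 90.1 cm). Posture compensation injects
constant deviations into maintenance channels (onset channels as offsets,
motion channels growing with the movement). Sensor error is modeled from
the published per-landmark magnitudes: the mean error becomes a per-trial
constant bias in a random direction, the SD becomes i.i.d. per-frame
Gaussian noise; both scale with `noise_scale`, and the hand marker (absent
from the published table) inherits the wrist magnitudes. Cohorts derive
per-trial seeds from a master seed via `numpy` seed sequences, so they are
bit-reproducible.

What passing tests show: the full pipeline recovers commanded ROMs within
1°, is monotone in ability, penalizes compensation, and preserves ability
rank (Spearman ≥ 0.9 over 30-trial cohorts) under published noise
magnitudes. What they do not show: performance on real hemiparetic
movement — spasticity, tremor, synergy patterns, trial-length variability,
occlusion and soft-tissue/clothing artifacts (the very effect that degrades
inward-rotation tracking clinically) are not modeled, and the noise model
is white where real tracking error is strongly autocorrelated. The T2
scorer is the most noise-sensitive of the three because pronation is read
from a hand marker only ≈ 8 cm from the wrist, so centimeter-level noise
becomes several degrees of angular noise in two of its ten features.
ROM itself, being a max-minus-min statistic, is extreme-value sensitive:
white landmark noise inflates a noisy trial's ROM by several degrees
(roughly the full range of the filtered angular noise over the trial), so
noisy absolute scores sit above their noise-free counterparts even though
the ability *ranking* is preserved; real tracking error, being strongly
autocorrelated, inflates ROM less than this white-noise model does.

## Numerical choices and degenerate inputs

- Trapezoidal centroid on a uniform grid; aggregation of an all-zero
  membership (no rule fired) is an error, not a default score.
- Membership clamping handles out-of-universe inputs; negative features are
  rejected at the feature-vector boundary.
- Degenerate axial-rotation samples become NaN and are excluded from
  reductions; > 50% degenerate in a window is an error.
- Sample SD uses the n−1 denominator and requires ≥ 2 samples.
- Filtering requires 2 × order + 1 frames and a cutoff below Nyquist.
- Fixed seeds make every simulation and random sweep reproducible; the
  same configuration and seed produce byte-identical JSON reports.

## Evaluation statistics

Agreement is the contingency-table trace over the total; Cohen's kappa uses
marginal-product expected agreement; correlations are sample Pearson
coefficients (per trial, per test, and on per-subject sums across the three
tests). The packaged clinical fixture (9 subjects × 3 tests, with clinician
three- and seven-point scores, system crisp scores and system continuous
scores) is the input for these statistics; one trial in it is a known
clinician/system disagreement, and the per-test correlation excluding it is
reported separately. Problem sizes used throughout the shipped tests and
acceptance script: 27-trial fixture, 30-trial synthetic cohorts, 100 random
rule firings per test for the engine-vs-oracle check, 200-point
monotonicity sweeps.
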