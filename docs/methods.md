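# Methods

This note documents the models, defaults and numerical conventions behind
`gazestate`, and what the synthetic tests do and do not establish.

## Display geometry and units

Gaze is recorded in screen pixels on a 511.8 × 288.3 mm, 1920 × 1080 px
display viewed from 500 mm. Conversion to degrees is per axis about the
screen centre, θ = arctan(offset_mm / 500 mm); amplitudes combine the two
axes Euclideanly. The conversion is odd and strictly monotone; x grows
rightward, y downward (screen convention). Event intervals are half-open
`[onset, offset)` over 0-based samples.

## Event detection

* **Velocity**: central difference over a centred ~10 ms window
  (5 samples at the 500 Hz default, scaled with rate). For a
  raised-cosine velocity profile this underestimates the peak by < 5 %,
  which bounds the peak-velocity recovery error asserted in the tests.
* **Blinks**: maximal runs of invalid pupil (≤ 0 or NaN) of at least
  20 ms, padded by 50 ms per side; reported duration includes the
  padding. Shorter dropouts are ignored.
* **Saccades**: maximal runs with speed > 30 °/s or acceleration >
  8000 °/s², at least 4 ms, outside padded blinks. Run edges are then
  extended outward while speed stays above 15 °/s so the slow tails of
  the velocity profile enter the amplitude; amplitude is the straight
  onset→offset displacement (not path length), average velocity is
  amplitude/duration, peak velocity the maximum in-run speed. Residual
  amplitude underestimation from the sub-15 °/s tails is ≈ 1 % at 4–5°
  and grows toward small saccades; it is common to both states and
  cancels in the normalized analysis.
* **Fixations**: the valid-sample complement of saccades ∪ blinks, kept
  when ≥ 40 ms. All thresholds are config-exposed
  (`events.DetectorConfig`); no recording hardware specifies them, so
  EyeLink-parser-like values were chosen.

## Per-trial indicators

Saccade amplitude statistics (mean, median, sample SD with n−1), mean
blink duration, and the means of per-saccade average and peak velocities.
"Sac Avg Velocity" is the mean of per-saccade average velocities (not
total path over total time). Indicators are computed per eye first and
merged binocularly as the arithmetic mean where both eyes are defined;
indicators with no contributing events are missing and excluded listwise.
The three repetitions of each condition are averaged into one value per
subject × paradigm × group before any group statistic — this is the
"unit" of every downstream analysis (36 fusion + 18 rivalry units per
paradigm in the 18-subject design).

Outliers are removed with the union of the box-plot rule
([Q1 − 1.5·IQR, Q3 + 1.5·IQR]) and the 3σ rule (sample SD), applied
within paradigm × state × indicator pools; which rule fired is recorded.
Fewer than 4 values pass through with a warning. The group percentage
display uses share-of-total across the three viewing groups (sums to
100 by construction; published percentage triples sum to ≈ 98–99, so the
exact variant used there is not recoverable).

## Statistical screen

All tests are two-sided. The interocular screen is a paired *t* per
indicator per paradigm at the Bonferroni-adjusted threshold; the family
size defaults to m = 38, which reproduces the published adjusted
α′ ≈ 0.0013 (m itself is not stated anywhere and is config-exposed).
The fusion-vs-rivalry comparison is gated by Shapiro–Wilk at 0.05 per
group: both normal → independent *t*; otherwise Mann–Whitney U (exact
enumeration when min(n₁, n₂) ≤ 8 and the groups are tie-free, otherwise
the normal approximation with continuity and tie correction). Type-I
calibration of the gated test is asserted at 5 % ± 1.5 % over 2000 null
replicates.

## Range discrimination

Within one paradigm, an indicator's units (both states; the two fusion
control groups are one fusion pool) are z-scored against the pool mean
and sample SD. Each state is summarised as mean ± SD of its z-values —
a deliberately simple interval summary covering ≈ 68 % of a Gaussian
state's mass. Conventions:

* **Overlap removal**: the intersection of the fusion and rivalry
  intervals is excised from both and kept as an abstention zone. A
  single shared boundary point is not an overlap. If one interval
  contains the other, the inner interval empties (flagged) and the outer
  keeps its larger remaining piece (flagged) — the procedure needs a
  single-interval result and the discarded sliver is the side facing the
  other state.
* **Cross-paradigm merge**: one state's intervals are intersected across
  paradigms ([max of lowers, min of uppers]). If the full intersection
  is empty, paradigms are dropped greedily, preferring those whose
  fusion-minus-rivalry direction opposes the majority (the hopping
  paradigm inverts the amplitude effect), trying larger subsets first;
  the included set is recorded. The merged "mean ± SD" is reported as
  midpoint ± half-width of the intersected interval — this convention
  exactly reproduces the published merged cells.
* **Classification** uses closed intervals; a z on a shared endpoint is
  indeterminate; outside both intervals is indeterminate. Reported
  values are rounded half-away-from-zero to 3 decimals, matching table
  conventions.
* **Evaluation**: because mean ± SD ranges abstain by construction,
  classifier accuracy is reported over determinate calls, with the
  abstention fraction alongside; merged ranges are only applied to units
  from the paradigms included in both state intervals.

The transcribed reference table contains one cell whose printed upper
endpoint (0.608) contradicts its own mean + SD (−0.608); the consistency
check treats an endpoint as valid when it equals mean ∓ SD within one
half rounding unit (0.0015) *or* is an overlap-trim: strictly inside the
raw interval and coinciding with the adjacent endpoint of the other
state (one velocity cell is of this kind). Exactly the sign-typo cell is
flagged; the printed range is still used for the merge, whose result is
unaffected either way.

## ROC evaluation

Positive class = rivalry. Scores are fitted probabilities from an
unpenalized maximum-likelihood logistic regression (Newton, tolerance
1e-8, ≤ 100 iterations, predictors standardized internally); perfect
separation falls back to capped finite coefficients and is flagged. The
ROC sweeps thresholds at every distinct score plus ±∞ sentinels
(score ≥ threshold ⇒ rivalry); AUC is trapezoidal over (FPR, TPR) with
tied-FPR vertices ordered by TPR, which makes it exactly the
Mann–Whitney pair-ranking probability with ties counted ½ (asserted
against a brute-force pair-counting oracle). The operating point
maximizes J = Sensitivity + Specificity − 1, ties broken toward the
lower threshold. No train/test split is used by default (resubstitution,
matching how such tables are usually reported); a clearly-labelled
k-fold mode exists. Per-paradigm indicator subsets follow the published
model choices: the static paradigm uses the three amplitude indicators
(blink duration excluded), the hopping paradigm excludes SD amplitude.

## Synthetic generator

The generator is a stated world, not a tuning dial: defaults encode the
study design (18 subjects, 3 paradigms × 3 groups × 3 repetitions;
trial durations 130/100/80 s; hopping target speed 4.5° per 1.2 s with
14 straight legs in 38 s then constant-speed arcs; S-shaped pursuit at
40 s per sweep, radius 5°) and the observed effect directions (static:
rivalry amplitude −, blink duration −; hopping: rivalry amplitude +,
hence velocities +; pursuit: rivalry amplitude −).

* **Sampling**: 500 Hz default (2 kHz-class hardware is config-reachable;
  500 Hz keeps desk-scale runtime). Tests shorten trials to 6–20 s;
  duration is a parameter, not a result.
* **Saccades**: Poisson-like onsets (exponential gaps, ≥ 120 ms apart,
  ~1–1.5 /s), amplitudes Normal(subject mean, CV × mean) clipped at
  0.8° (so every true saccade exceeds the detector's velocity threshold);
  raised-cosine velocity profile with peak = 50 (°/s)/° × amplitude
  capped at 700 °/s (duration 2A/v_peak ≈ 40 ms); headings uniform with
  a re-centering bias beyond a leash, keeping gaze near the target.
  Ground-truth amplitudes and peak velocities are measured on the
  noiseless trace, so they are exact oracles for the detector.
* **Blinks**: ~0.2 /s, Normal(250 ms, 40 ms) ≥ 80 ms, scheduled clear of
  saccades and trial edges; pupil = 0 and gaze invalid for the duration
  (no half-closed-lid modelling).
* **Between-subject structure**: per subject × paradigm trait offsets for
  amplitude mean (SD 0.35°), blink duration mean (SD 25 ms) and
  amplitude CV (0.25 ± 0.05), shared across that subject's groups.
* **Effect sizes** are specified in z-pool SD units — the scale of the
  normalized analysis itself, where the published state gaps are ≈ 1.6 —
  with defaults −1.5 (static amplitude), +1.0 (hopping amplitude, and
  thereby velocities via the main sequence), −1.5 (pursuit amplitude),
  −1.0 (static blink duration). The physical shift solves
  gap = e·σ_b / √(1 − w(1−w)e²) with w = 2/3 the fusion share, because
  the pooled SD itself widens with the gap; extreme e saturates at the
  amplitude floor. No physical-unit effect sizes are published; these
  magnitudes are the package's calibration choices and are not revisited.
* The two fusion groups (R-R, G-G) draw from identical distributions.

**What a green test establishes**: that each stage implements its
contract and that the chain separates states when the stated effects are
present (static-paradigm logistic AUC 0.99 at 18 subjects, seed 0) and
not when they are absent (null AUC 0.55). It does **not** establish the
published real-data effect magnitudes, AUCs (0.990/0.741/0.967) or
correlation values, which require the deposited recordings; the
generator also omits perceptual alternation dynamics within rivalry
trials, microsaccadic/fixational physiology, pursuit gain < 1, and
glissades.

## Degenerate inputs and numerics

Zero saccade/blink rates yield event-free trials (gaze SD ≈ the noise
SD); zero pool SD, empty interval lists, single-class ROC inputs and
n < 2 state ranges raise; n < 3 pairs and n < 3 group cases raise;
constant predictors raise. Interval emptiness is encoded as
lower > upper; all interval operations are exact floating-point
comparisons with closed endpoints. Table rounding is half-away-from-zero
to 3 decimals with a 1e-9 guard against representation error.
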