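# Methods

This note documents the models, parameter choices and numerical
conventions behind `dyadkin`, and what the synthetic test bed does and
does not establish about real recordings.

## Data model

A `Recording` is one person's full-session time series: 7 trackers × 6
degrees of freedom (x, y, z in mm; azimuth, elevation, roll in degrees)
at 240 Hz, plus the 3D position of the board's start marker. Sessions
are continuous — ten 20 s action trials separated by 5 s rests — so
trial boundaries are *detected*, not assumed. The on-disk format is one
wide CSV per person with `# key: value` metadata lines; the reader maps
columns by header name, rejects non-finite cells (the source device
streams continuously, so gaps indicate corruption rather than missing
data), and converts device-native position units to mm via a scale
factor. Round-trips are exact: values are written with 17 significant
digits and parsed with correctly-rounded float conversion.

## Preprocessing

Five steps, applied in a fixed order; each is also callable on its own.

1. **Despike.** Acceleration is the twice-applied first difference
   (left-aligned; the value at difference index *j* is centred on
   original sample *j*+1). Samples whose acceleration deviates more than
   3 SD from the acceleration mean (mean and SD over the whole session,
   per channel, since despiking precedes trial definition) are spike
   candidates. A single bad sample splashes across three consecutive
   acceleration values, so candidates within two samples of each other
   are coalesced and the largest deviation is flagged; this makes
   detection of an isolated spike exact (one flag at the spike). The
   flagged sample and its immediate neighbours are replaced by linear
   interpolation across the bracket [i−2, i+2] — the fewest samples that
   remove both the spike and its differentiation splash. Single pass: a
   despiked series is not despiked again. More than 10% flagged raises a
   "likely corrupt" warning; note that with a global 3 SD threshold the
   flaggable fraction is mathematically bounded near 1/9, so the warning
   indicates pathological, heavily contaminated input.
2. **Filter.** Zero-phase (forward–backward) Butterworth low-pass,
   order 4, cutoff 15 Hz. Two passes put the amplitude response at the
   cutoff at 0.5 (−3 dB each pass). Edge handling uses odd-reflection
   padding of length 3·(order+1); the choice only affects edge samples.
3. **Rotate (actor, video condition only).** The video condition tilts
   the actor's board 13° anticlockwise so the camera sees it squarely;
   the correction applies *x′ = x cos13 − y sin13*,
   *y′ = y cos13 + x sin13* samplewise to every tracker's x/y (and to
   the start marker). Orientation channels are never rotated — the
   correction is defined on x and y only. (In a right-handed frame these
   formulas are a counterclockwise rotation; they are implemented
   verbatim as the defining convention.)
4. **Latency shift (imitator, video condition only).** All channels are
   advanced by round(0.111 s × 240 Hz) = 27 samples, compensating the
   measured camera-to-projection latency; the vacated tail repeats the
   final sample. Rounding to a whole sample avoids resampling; the
   residual (< 2 ms) is far below the lag-scan resolution of interest.
5. **Segment.** Trials are maximal runs where the index fingertip's 3D
   distance from the start marker exceeds 100 mm for longer than 5 s;
   shorter excursions are false starts. Segmentation runs on the actor,
   and the actor's windows are applied to the paired imitator (imitators
   start on the actor's cue). At most the first 10 windows are kept.

Orientation channels are unwrapped (period 360°) before any
differencing or correlation, and are despiked and filtered like
positions — applying the artifact model uniformly across channels is
this package's choice.

## Derived variables

Seven per person. With shoulder S, elbow E, wrist W and the auxiliary
origin O = (x_S, y_S, z_E) (so S→O is vertical):

* q₁ = cos⁻¹((z_S − z_E)/|ES|) — upper-arm elevation from vertical;
* q₂ = cos⁻¹((y_S − y_E)/|EO|), |EO| from x and y only — horizontal
  direction of the shoulder→elbow displacement against the y axis;
* q₃ = cos⁻¹((|SW|² − |ES|² − |EW|²)/(2|ES||EW|)) — elbow angle by the
  cosine rule. This expression gives 0° for a straight (collinear) arm
  and 90° for a right angle at the elbow, i.e. 180° minus the
  triangle's interior angle; it is implemented exactly as defined and
  the naming ("elbow angle") should be read with that convention.

Cosine arguments are clamped to [−1, 1] before arccos (floating
round-off otherwise yields NaN at collinear configurations; the clamp
changes nothing beyond ~1e−15). Genuinely degenerate samples
(zero-length |ES|, |EW| or horizontal |EO|) yield NaN and are counted,
with a warning above 1%. Grip aperture is the 3D index–thumb distance;
grip position the samplewise midpoint. All derived series have exactly
the source length, so trial windows index into them unchanged. These are
surface-marker estimates, not joint-centre angles, and q₃ ignores wrist
rotation.

## Coupling

For each lag ℓ ∈ [−1200, +1200] samples (±5 s at 240 Hz), Pearson's r is
computed between a[t] and b[t+ℓ] over the n−|ℓ| overlapping samples,
using the overlap's own means and variances — no zero padding or global
normalization, which would bias r at large lags. Lags whose overlap
falls below half the trial length (default `min_overlap_frac = 0.5`) are
undefined, preventing spurious |r| ≈ 1 from tiny overlaps. Positive lag
means the imitator follows the actor; the convention is fixed here
because correlation lag signs are otherwise ambiguous.

Implementation: both series are pre-centred on their global means (which
leaves per-overlap Pearson r unchanged) and the per-lag sums are built
from an FFT cross-correlation plus prefix sums, so a full ±1200-lag scan
of a 4800-sample trial costs milliseconds. The test suite pins this
against a definitional per-lag Pearson loop to 1e−10.

The absolute-maximum |r| and its lag summarize each trial; ties in |r|
break toward the smallest |lag|, then toward the negative lag
(deterministic, favouring the parsimonious alignment). Trials are
averaged arithmetically (after Fisher transformation for the Z summary,
below); trials excluded by the caller or yielding undefined curves are
skipped. The exploratory surface maps apply the same machinery to every
ordered actor-channel × imitator-channel pair (42×42).

## Statistics

Per-trial absolute-maximum r values are Fisher-transformed
(Z = ½ ln((1+r)/(1−r))) *before* averaging across the trials of a
condition — standard practice for aggregating correlations; the
alternative reading (average r, then transform) is one config flag away
(`z_before_mean = false`). r = 1 (possible on noiseless synthetic data)
is clipped to 1 − 1e−7 with a warning. The transform is applied to the
absolute maximum, so Z ≥ 0; signed r is retained in outputs.

The 2×2 within-subject design is tested on per-person condition means.
Each effect (feedback, difficulty, interaction) reduces to a per-person
contrast; the univariate test is the one-sample t on that contrast,
reported as F = t² with df (1, n−1) and partial η² = F/(F + n−1). The
multivariate test on a DV triple is the one-sample Hotelling T² on the
3-vector of contrasts, reported as the exact F = ((n−p)/(p(n−1)))·T²
with df (p, n−p) — for 2-level factors all the classical multivariate
criteria (Pillai, Wilks, Hotelling–Lawley) coincide with this F. With
n = 12 subjects this yields the design's df of (1, 11) and (3, 9).
Degenerate inputs are explicit: identical cells per person give F = 0,
p = 1; zero contrast variance with nonzero mean is an error. The test
suite cross-checks the univariate route against an independent
repeated-measures ANOVA implementation and verifies 5% ± 2% type-I
calibration over 1000 null tables.

## Synthetic dyads

The generator emulates the pegboard game so every pipeline stage has a
known target:

* **Board**: 4×4 rods at 60 mm spacing, heights 30/70/110/150 mm
  front-to-back, 40 mm balls, start marker at the near-right corner
  placed so every grasp point lies well outside the 100 mm
  trial-detection radius.
* **Moves**: 10 legal adjacent-peg (never diagonal) moves per trial to
  unoccupied rods; simple difficulty walks one ball, complex partitions
  the 10 moves over all three balls (each at least once). Dead-ended
  walks re-seed from a fresh placement.
* **Hand path**: minimum-jerk point-to-point segments
  (s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, zero endpoint velocity/acceleration), with
  transports arcing through a via-point 30 mm above the taller rod. The
  trial's 20 s is split uniformly across one reach, ten moves and one
  return (the protocol fixes move counts and trial time but not
  per-move speed; a uniform split is the least-informative choice).
  Aperture opens to 60 mm for empty reaches, holds ~42 mm around the
  40 mm ball, and closes to 30 mm on the start marker.
* **Arm**: the wrist rides a fixed offset behind the grip; the elbow
  follows two-link inverse kinematics (upper arm 300 mm, forearm
  260 mm, shoulder fixed 150 mm behind and 400 mm above the board
  edge, elbow-down solution in the vertical plane) — plausible adult
  geometry whose only job is smooth, in-range joint angles. Shoulder
  and head carry low-amplitude drift; orientation channels are
  low-amplitude signals driven by smoothed tracker speed, present so
  all 42 channels are analyzable, not biomechanically faithful.
* **Imitator**: each channel delayed by round(lag × fs) samples (edges
  padded with rest posture), scaled by a gain about its mean, plus
  low-passed (8 Hz) Gaussian noise — orientation channels receive 10%
  of the position noise SD, matching their smaller amplitude scale.
* **Video-condition artifacts**: the raw actor arrives rotated −13°
  (the tilted board) and the imitator's effective delay includes the
  27-sample presentation latency, so the preprocessing corrections are
  exercised end-to-end rather than vacuously.

### Condition scenario

The default degraded-video scenario sets behavioral lag 0.65 s
(face-to-face) vs 0.80 s (video), +0.15 s in complex difficulty, and
coupling noise 25 mm vs 35 mm, +10 mm in complex. These were chosen
once so the simulated grip-position coupling lands in the empirically
reported regime (mean Z ≈ 1.1–1.5, i.e. r ≈ 0.8–0.9; mean lags
≈ 0.6–0.8 s) with the face-to-face > video and simple > complex
ordering; they are a scenario, not an estimate of any individual dyad.

### What passing tests do and do not show

The generator produces an imitator that is *by construction* a lagged
linear copy of the actor plus stationary noise. Tests therefore
establish that the pipeline recovers known lags to one sample, orders
conditions correctly, and is statistically calibrated — they do not
establish that real imitation is a lagged linear copy. Real recordings
add nonstationary strategy changes, anatomical differences between
partners, tracker slippage and field distortions near metal, none of
which the generator models (only its single-sample spike artifact is
modelled). Headline F and p values from the original 12-participant
study depend on those recordings and are deliberately out of scope.

## Problem sizes and determinism

All randomness flows from one `numpy` `Generator` passed explicitly;
fixed seeds reproduce sessions bit-for-bit. The test suite runs
full-scale sessions (ten 20 s trials at 240 Hz, 58 800 samples × 42
channels) where the property under test depends on scale (lag recovery,
direction recovery) and 2-trial sessions elsewhere; the acceptance
script uses full-scale sessions for lag recovery and the condition
scenario (10 seeded dyad pairs), 1000 simulated n=12 tables for
calibration, and 10 replicates of 5 injected spikes for despike
analytics.

## Known limitations

* The lag scan assumes one dominant alignment per trial; time-varying
  lags (e.g. within-trial catch-up) are averaged over. Windowed or
  coherence-based variants are out of scope.
* Orientation channels are correlated after unwrapping, with no
  circular statistic, mirroring the uniform treatment of all six DOFs.
* The multivariate test assumes the contrast covariance is full rank;
  with p = 3 DVs it needs n ≥ 4 subjects (n ≥ p+1).
* The device's native units are not standardized; the reader's scale
  factor must be set from the device configuration (mm conventions here
  follow the reported board geometry).
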