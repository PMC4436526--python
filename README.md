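# dyadkin

Analysis pipeline for **two-person imitation kinematics**: how accurately
(and with what delay) one person copies another's object-directed
movements, measured with multi-tracker motion capture.

The setting is an imitation game: an *actor* freely transports balls
across a 4×4 pegboard (10 adjacent-peg moves per 20 s trial, 10 trials
per session) while an *imitator* copies the movements, either
face-to-face or through a live video projection, with simple (one ball)
or complex (three balls) difficulty. Both people wear seven 6-DOF
electromagnetic trackers (head, shoulder, elbow, wrist, thumb, index,
little finger) sampled at 240 Hz: position x/y/z in mm plus
azimuth/elevation/roll in degrees — 42 channels per person.

`dyadkin` is aimed at motor-control and social-interaction researchers
who want a reproducible route from raw dyadic tracker recordings to
condition-level statistics, plus a fully synthetic test bed when no
recordings are available.

## What it computes

1. **Preprocessing** (five steps, in order): despiking of single-sample
   artifacts flagged at >3 SD of each channel's double-differenced
   (acceleration) series; bidirectional 4th-order Butterworth low-pass at
   15 Hz; a 13° in-plane rotation *x′ = x cos13 − y sin13*,
   *y′ = y cos13 + x sin13* correcting the tilted board in the video
   condition (actor only); a 111 ms backward shift compensating video
   presentation latency (imitator only); and trial segmentation — maximal
   runs where the index fingertip is >100 mm from the start marker for
   >5 s (shorter excursions are false starts).
2. **Derived variables** per person: arm joint angles
   q₁ = cos⁻¹((z_S − z_E)/|ES|), q₂ = cos⁻¹((y_S − y_E)/|EO|),
   q₃ = cos⁻¹((|SW|² − |ES|² − |EW|²)/(2|ES||EW|)); grip aperture
   (index–thumb distance); and 3D grip position (index–thumb midpoint).
3. **Coupling**: for each trial, the imitator series is shifted sample by
   sample over lags of −5…+5 s and Pearson-correlated with the actor
   series on the overlap at each lag; the absolute-maximum *r* and its
   lag summarize the trial (positive lag = imitator follows). An
   exploratory mode computes the full 42×42 channel-pair surface maps.
4. **Statistics**: per-trial *r* is variance-stabilized with the Fisher
   transformation Z = ½ ln((1+r)/(1−r)), averaged across trials, and the
   2×2 feedback × difficulty within-subject design is tested with
   univariate F tests (df (1, n−1)) per variable and a multivariate
   Hotelling-T²-based F (df (3, n−3)) per variable triple.
5. **Synthetic dyads**: a generator builds actor sessions from legal
   pegboard move sequences and minimum-jerk hand paths (with a two-link
   arm model behind the wrist), and imitators as lagged, gain-perturbed,
   noise-corrupted copies — with a ground-truth ledger so pipeline
   recovery is checkable exactly.

## Worked example

```python
import numpy as np
import dyadkin as dk

rng = np.random.default_rng(0)
cond = dk.CrossedCondition(dk.Feedback.face_to_face, dk.Difficulty.simple)
session = dk.simulate_dyad(cond, rng, person_id="pair01")
analysis = dk.analyze_dyad(session.actor, session.imitator)

summary = (
    analysis.trial_results.groupby("dv", sort=False)[["r_abs", "lag_s"]]
    .mean()
    .round(3)
)
print(f"{len(analysis.windows)} trials detected")
print(summary)
```

prints

```
10 trials detected
          r_abs  lag_s
dv
q1        0.709  0.656
q2        0.523  0.982
q3        0.542  0.599
aperture  0.188 -0.842
grip_x    0.899  0.605
grip_y    0.903  0.608
grip_z    0.852  0.639
```

Reading: the grip position — the task-level variable tracking where the
ball is being carried — couples strongly (|r| ≈ 0.85–0.90) with the
imitator trailing by ~0.6 s (the scenario's generative lag is 0.65 s);
joint angles couple moderately; grip aperture couples weakly because both
people hold a constant grip for most of each transport, exactly the
pattern seen in real dyads.

The same flow is available from the shell:

```bash
dyadkin simulate --seed 1 --out-dir sim/
dyadkin preprocess --actor sim/face_to_face_simple/actor.csv \
    --imitator sim/face_to_face_simple/imitator.csv --out-dir clean/
dyadkin analyze --actor sim/face_to_face_simple/actor.csv \
    --imitator sim/face_to_face_simple/imitator.csv --out-dir results/f2f_simple
dyadkin summarize --results-dir results/ --out summary.csv
```

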