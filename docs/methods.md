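# Methods

This note documents the models, conventions and numerical choices the
package is built on, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the problem was genuinely
open.

## Frames and rotation conventions

World frame: X points to magnetic north (the anterior direction at
calibration), Y left, Z up; gravity is −Z, so a static accelerometer
measures the reaction +Z in units of g. Head frame: X anterior, Y left
(through the ears), Z up. A direction cosine matrix (DCM) *R* maps
head-frame vectors to world-frame vectors; every `RotationState`
carries a consistent unit-quaternion/DCM pair (orthonormality and
det = +1 enforced to 1e−9, with a Procrustes re-projection for inputs
within 1e−6 of a rotation).

Cervical angles use the YZX Euler factorisation
*R* = *R*<sub>Y</sub>(α)·*R*<sub>Z</sub>(rot)·*R*<sub>X</sub>(incl):
flexion-extension α about the lateral axis is extracted first (it
drives the vertical cursor coordinate exclusively), then axial rotation
about the vertical axis, then lateral inclination about the anterior
axis. The closed-form decomposition reads the middle row and first
column of the composed matrix; it is degenerate when |cos(rot)| ≤ 1e−7
(axial rotation within ~6e−6° of ±90°), where a `GimbalLockError`
names the axes that have collapsed. Head poses in cervical exercise
stay tens of degrees away from this singularity.

## Sensor fusion

The angular-rate integration uses the trapezoid of consecutive gyro
samples applied as a body-frame rotation vector. Correction is an
explicit complementary filter: the measured gravity direction and the
horizontal component of the measured magnetic field are compared with
their predictions, and a fraction `gain` of the combined error angle is
applied per sample. `gain` defaults to 0.02 at the 50 Hz default rate
(time constant ≈ 1 s): fast enough to absorb gyro drift over a 210-s
session, slow enough not to track transient accelerations. The
magnetometer is projected onto the horizontal plane before comparison
so it can never disturb tilt. The initial attitude comes from a TRIAD
solution on the first accel/mag sample, which makes a world-aligned
static stream start exactly at identity. The filter is deliberately not
a Kalman-class estimator: for slow head motions a single-gain
complementary filter is deterministic, transparent and accurate to a
fraction of a degree (RMS ≈ 0.15° on clean 60-s streams in the tests).

Calibration fuses the stream and takes the chordal mean (element-wise
mean matrix projected to the nearest rotation — deterministic and
invariant to sample order) over the trailing `window_s` seconds,
defaulting to 2 s: the posture at the moment the operator confirms. A
maximum angular deviation of 5° from the mean within the window guards
against calibrating a moving head.

## Mapping

The cursor law is the linear proportional form *x* = *R*<sub>H</sub>·β/β<sub>T</sub>,
*y* = −*R*<sub>V</sub>·α/α<sub>T</sub>: an angle equal to the
configured range of motion lands exactly on the configured extent,
which is what "required ROM to reach the targets" means operationally.
The relative rotation is *R*<sub>cal</sub><sup>−1</sup>·*R*<sub>S</sub>
(the alternative order would not send the neutral posture to the screen
centre). Out-of-range angles clamp to the screen rather than erroring:
the airplane must stay in the play area. Whether extents denote
half-extents from centre or full inter-target distances was ambiguous;
half-extents from centre were chosen and are used consistently by the
target generator and simulator. Defaults (extents 400 × 300 px inside a
1280 × 720 screen, α<sub>T</sub> = β<sub>T</sub> = 25°) sit mid-way in
the easy-level 20–30° mobility band.

## Game engine

One target is active at a time; a target counts as reached at the first
cursor sample strictly inside its radius during its 5-s window (no
dwell requirement — the simplest rule consistent with "picking up" a
target; a dwell could be added as a config extension). A reached target
disappears but the cadence is fixed, so session duration is always
`targets_per_series × n_series × inter_target_s` (210 s under the
default protocol). Target radius defaults to 40 px (not dictated by the
protocol; ≈3.3° of flexion at the default mapping, a plausibly sized
on-screen token) and is configurable. Target positions are uniform over
the ±`required_rom` angular box with a ≥ `min_separation` (5°)
rejection-sampled distance from the previous target, so consecutive
targets always demand a movement. The session score is the percentage
of scheduled targets reached; with equal series lengths this equals the
mean of the per-series percentages, which is also reported.

## Synthetic users

Pursuit is first-order: the head approaches the aimed angles
exponentially (time constant `tau_s` = 0.3 s) with the per-axis rate
capped at `max_angular_speed` (60 deg/s default). Between goal switches
this has a closed form (a constant-rate phase while the demanded rate
exceeds the cap, then an exponential tail), evaluated segment by
segment — the simulator is exact, fast and free of integration error.
Goals switch `reaction_delay` (0.4 s) after each spawn.

Motor noise has two parts, both scaled by `motor_noise_sd`: a per-target
aiming error (SD = `motor_noise_sd` per axis, drawn once per target —
mis-reaching) and a continuous tremor/wander, an AR(1) process with SD
one quarter of `motor_noise_sd` and 0.5 s correlation time. The tremor
is correlated rather than white because white per-sample jitter would
give a player hundreds of independent chances to clip a target per
window and make misses essentially impossible at any realistic
amplitude. The default `motor_noise_sd` = 3.2° makes a first-session
player reach about 69% of targets under the default protocol, the
success level a naive older-adult player shows at the start of
training. Learning multiplies the noise by `learning_rate` (0.9) each
session; with 8 sessions this carries the mean score from ≈69% into the
low 90s, reproducing the qualitative training trend. Learning is
modelled as noise decay only — one interpretable knob — with reaction
delay and speed held fixed.

The inverse sensor model differentiates the orientation sequence for
body-frame angular rates (forward difference, last sample repeated),
rotates gravity and the magnetic reference into the head frame, and
adds Gaussian white noise per channel plus a constant per-stream gyro
bias. Default noise (gyro 0.2 deg/s, bias 0.05 deg/s, accel 0.01 g,
mag 0.01) is typical of a consumer MEMS unit after factory calibration.

What the simulator does **not** emulate: biomechanical coupling between
cervical axes, fatigue and pain dynamics, non-Gaussian or correlated
sensor errors (hard/soft-iron magnetic distortion, accelerations from
body sway), and dropped samples. Tests passing on this generator
therefore validate the pipeline's logic and numerics, not its
robustness to every artefact of real recordings.

## Questionnaires

SEQ reversal uses the standard Likert transform 6 − raw on Q7–Q10, Q12
and Q13; totals are integers in [13, 65]. The open-ended question is
stored verbatim and never scored. NDI percent is 100·raw/50. The MMSE
education adjustment (±1 error allowed per category by education level)
belongs to the error-count reading of the instrument and is not applied
to the 35-point score classification; the record keeps the education
level so callers can apply it when working with error counts. The VAS
is consumed as data: validation to [0, 10] and a poor-control flag
above 3 points.

## Trial statistics

All tests are two-sided at α = .05. Paired comparisons use Student's t
for related samples; identical samples return the degenerate no-effect
result (t = 0, p = 1) while a nonzero constant difference (undefined t)
raises. Wilcoxon signed-rank uses the exact null distribution up to 25
nonzero untied differences and the normal approximation with continuity
correction otherwise; the positive-rank sum is reported alongside
scipy's statistic. The residual analysis (week 0 vs week 8) escalates
to per-sequence Wilcoxon tests when significant; the period analysis
compares weeks 4 and 12; the sequence analysis compares per-subject
within-treatment changes between arms with a pooled-variance two-sample
t test — the comparison test was an open choice, and an unpaired t is
the natural one for two independent groups of subjects. Missing data
are refused everywhere, never imputed (completers-only analysis).

The repeated-measures ANOVA is the classical one-way
sums-of-squares decomposition (session and subject main effects,
F = MS<sub>sessions</sub>/MS<sub>error</sub> on (k−1, (n−1)(k−1)) df,
no sphericity correction), implemented directly — it is a three-line
computation that the calibration simulations call thousands of times —
and cross-checked in the tests against both a loop-level
sums-of-squares oracle and `pingouin.rm_anova`.

The synthetic crossover generator models a pain-type outcome additively
around subject baselines (default 5.4 ± 1.8, a chronic neck-pain
cohort) with injectable treatment effects, carryover and period shifts
and 0.8-SD measurement noise, balanced arms. It exists to calibrate and
power-check the analyses; it does not model dropout, floor effects, or
correlation between baseline severity and treatment response.

## Problem sizes and determinism

Simulation-based checks use fixed seeds throughout: 1,000 simulated
nulls for the type-I calibrations, 500 replicates for the
learning-trend property, 150 replicates at n = 100 subjects for
effect-recovery bias, and sessions simulated at 50 Hz. These sizes give
Monte-Carlo standard errors comfortably below the margins being tested
while keeping the full suite quick. Every random path flows through an
explicit `numpy.random.Generator`; identical seeds give bit-identical
streams, trajectories, logs and scores end-to-end.

## Known limitations

The fusion gain is fixed, not adaptive; severe magnetic disturbance
would corrupt heading (mitigate with `mag_enabled=False`, which leaves
yaw to the gyro). The engine's hit rule has no dwell time and no target
re-display after a miss. The user model's learning curve is exponential
in noise only and cannot reproduce plateaus or day-to-day variability.
The crossover analyses are the classical two-stage procedures, not a
mixed-effects model of the full five-assessment profile.
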