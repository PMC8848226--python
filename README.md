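# cervigame

A headless, fully testable re-creation of the software chain behind an
IMU-driven serious game for cervical (neck) exercise, together with the
instruments and statistics used to evaluate such a game in a crossover
pilot trial. It is aimed at rehabilitation-technology researchers who
want to prototype, simulate or analyse head-pointer exercise protocols
without the sensor hardware or the game GUI.

## What it implements

**Head tracking.** A head-worn inertial unit streams gyroscope (deg/s),
accelerometer (g) and magnetometer samples. A complementary filter
integrates the gyroscope and corrects tilt and heading with the
accelerometer/magnetometer, producing a direction cosine matrix
*R*<sub>S</sub> per sample. Holding a neutral upright posture for 2 s
calibrates the reference orientation *R*<sub>cal</sub>.

**Absolute mapping.** The cursor (a virtual airplane) is driven
memorylessly by the orientation relative to calibration,

&nbsp;&nbsp;&nbsp;&nbsp;*R*<sub>T</sub> = *R*<sub>cal</sub><sup>−1</sup> · *R*<sub>S</sub>,

whose YZX Euler angles (flexion-extension α first, then axial rotation,
then lateral inclination) map linearly to pixels:

&nbsp;&nbsp;&nbsp;&nbsp;*y* = −*R*<sub>V</sub> · α ⁄ α<sub>T</sub>, &nbsp;&nbsp; *x* = *R*<sub>H</sub> · β ⁄ β<sub>T</sub>,

where *R*<sub>H</sub>, *R*<sub>V</sub> are the screen extents in pixels
and α<sub>T</sub>, β<sub>T</sub> the range of motion (degrees) needed to
reach them; β is lateral inclination or axial rotation, configurable.
Flexion moves the airplane down; the same head pose always gives the
same cursor position.

**Game engine.** Sessions follow the pilot protocol by default: 2
series × 21 targets, one every 5 s (210 s total), targets drawn
uniformly over the angular range-of-motion box. A target is reached
when the cursor enters its radius before the next spawn; the session
stores the trajectory, per-target outcomes and the percentage score.

**Synthetic users.** A parametric player model (reaction delay, capped
angular speed, per-target aiming error plus correlated tremor,
engagement probability, and multiplicative noise decay across sessions)
pursues the targets; an inverse sensor model turns any angular
trajectory back into raw IMU signals, closing the loop for end-to-end
tests.

**Clinical instruments.** SEQ (13 Likert items, reverse-keyed
Q7–Q10/Q12/Q13, total 13–65), NDI (10 items 0–5, percent of 50), MMSE
(35-point adaptation, severity brackets, age-dependent cutoff 24/29)
and VAS validation (0–10, poor control above 3).

**Crossover statistics.** Paired t and Wilcoxon signed-rank
comparisons; the design-specific residual (baseline vs post-washout,
with per-sequence Wilcoxon escalation), period (week 4 vs 12) and
sequence (A-B vs B-A change comparison) analyses; Shapiro-Wilk
annotation; and a one-way repeated-measures ANOVA over session scores.

## Worked example

```python
import numpy as np
from cervigame import GameConfig
from cervigame.engine import series_scores
from cervigame.simulator import UserModel, simulate_session

log = simulate_session(UserModel(), GameConfig(), np.random.default_rng(7))
print(f"{log.n_reached}/{len(log.outcomes)} -> {log.score_percent:.2f}%")
print([f"{s:.1f}%" for s in series_scores(log)])
```

prints

```
30/42 -> 71.43%
['76.2%', '66.7%']
```

— a moderately skilled simulated player reaches 30 of the 42 scheduled
targets (71.43%), with the two series at 76.2% and 66.7%. The
`examples/` directory holds one narrative script per capability
(head-tracking pipeline, session play, questionnaire scoring, crossover
analysis); each prints its numbers and what they mean. A thin CLI
(`cervigame simulate|replay|score|analyze|report`) exposes the same
pipeline from the shell.

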