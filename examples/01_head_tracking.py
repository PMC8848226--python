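"""From raw IMU samples to head angles and an on-screen cursor.

Builds a synthetic recording (2.5 s neutral hold, then a slow nod),
fuses it, calibrates the neutral posture and maps each orientation to
airplane coordinates.
"""

import numpy as np

from cervigame import MappingConfig, calibrate, decompose_yzx, fuse_imu
from cervigame.fusion import ImuStream
from cervigame.mapping import cursor_from_orientation, relative_rotation
from cervigame.simulator import ImuNoise, PursuitTrajectory, synthesize_imu

rate = 50.0
t = np.arange(0, 10, 1 / rate)
# neutral for 2.5 s, then flexion swinging to ~15 degrees
alpha = np.where(t < 2.5, 0.0, 15.0 * np.sin(2 * np.pi * 0.2 * (t - 2.5)))
traj = PursuitTrajectory(t, alpha, np.zeros_like(t), np.zeros_like(t))
stream = synthesize_imu(traj, ImuNoise(), np.random.default_rng(0))

r_cal = calibrate(ImuStream([s for s in stream if s.t <= 2.5]), window_s=2.0)
cfg = MappingConfig()

print("t [s]   flexion [deg]   cursor y [px]")
for k, (tk, r_s) in enumerate(fuse_imu(stream)):
    if k % 100 or tk < 2.5:
        continue
    r_t = relative_rotation(r_cal, r_s)
    e = decompose_yzx(r_t)
    pos = cursor_from_orientation(r_t, cfg)
    print(f"{tk:5.1f}   {e.alpha:+13.2f}   {pos.y:+12.1f}")

print("\nFlexion (head nodding down) moves the airplane down the screen;")
print("with alpha_t = 25 deg and r_v = 300 px, 15 deg of flexion is -180 px.")
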