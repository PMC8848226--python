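"""One simulated training session under the pilot protocol.

A synthetic player (reaction delay, speed cap, motor noise) pursues the
42 scheduled targets; the engine scores the session and summarises the
airplane trajectory.
"""

import numpy as np

from cervigame import GameConfig
from cervigame.engine import series_scores, trajectory_metrics
from cervigame.simulator import UserModel, simulate_session

cfg = GameConfig()  # 2 series x 21 targets, one every 5 s -> 210 s
user = UserModel()  # defaults: 0.4 s reaction, 60 deg/s cap, 3.2 deg noise

log = simulate_session(user, cfg, np.random.default_rng(7))

print(f"targets reached : {log.n_reached}/{len(log.outcomes)}")
print(f"session score   : {log.score_percent:.2f}%")
print(f"series scores   : {[f'{s:.1f}%' for s in series_scores(log)]}")
m = trajectory_metrics(log)
print(f"path length     : {m['path_length_px']:.0f} px")
print(f"mean time-to-hit: {m['mean_time_to_hit_s']:.2f} s")
print(f"idle fraction   : {m['idle_fraction']:.2f}")
print("\nThe score is the percentage of targets whose radius the airplane")
print("entered before the next target spawned; time-to-hit is measured from")
print("each target's appearance.")
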