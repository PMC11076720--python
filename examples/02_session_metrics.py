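"""Per-session metrics: engagement, trajectory fitness, 20-feature summary.

Engagement is the share of the task's required arm work the patient
actually delivered; fitness is the R^2 (x100) between the actual and the
preset trajectory.
"""

import numpy as np

from rehabdss import (
    SessionSignals,
    TrajectoryPair,
    WorkMeasurements,
    compute_engagement,
    compute_fitness,
    extract_features,
)

# work measurements for one task: total 10 J, robot did 7 J during training,
# 4 J unloaded -> the arm supplied 3 J of the 6 J it was asked for
w = WorkMeasurements(w_total=10.0, w_motor=7.0, w_robot=4.0)
print(f"engagement: {compute_engagement(w):.1f} %  (arm delivered {w.w_user:.0f} J of {w.w_arm:.0f} J)")

# a noisy tracking of a sine preset
t = np.linspace(0, 2 * np.pi, 200)
preset = np.sin(t)
rng = np.random.default_rng(0)
actual = preset + rng.normal(0, 0.15, t.size)
fit = compute_fitness(TrajectoryPair(actual=actual, preset=preset))
print(f"fitness: {fit:.1f} %  (100 = perfect tracking of the preset trajectory)")

# condense a session into its 20 summary statistics
session = SessionSignals(
    force=rng.gamma(2.0, 0.5, 500),
    velocity=np.clip(rng.normal(0.07, 0.03, 500), 0, None),
    fitness_trace=np.clip(rng.normal(78, 15, 500), 0, 100),
    engagement_trace=np.clip(rng.normal(37, 22, 500), 0, 100),
    mode="passive",
)
f = extract_features(session)
print(f"features extracted: {len(f.values)} (5 statistics x 4 signals)")
print(f"  mean engagement {f['mean_engagement']:.1f} %, mean velocity {f['mean_velocity']:.3f} m/s")
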