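"""Score climbing, appetitive memory, and open-arena locomotion.

All three assays reduce to the standard formulas: the geotaxis
performance index, the reciprocal-pair memory index with its
fewer-than-15-flies discard rule, and the per-fly walking metrics with
the 4 mm/s walking threshold.
"""

from flycount3d import (
    ClimbingTrial,
    ConditioningTest,
    climbing_pi,
    locomotion_metrics,
    make_trajectories,
    memory_pi,
)

# climbing: 10 flies, 6 above the top line, 2 below the bottom line
pi = climbing_pi(ClimbingTrial(ntot=10, ntop=6, nbot=2))
print(f"climbing PI = {pi}")  # 1.0 = all at top, 0.0 = all at bottom

# memory: reciprocal halves (15 vs 5 of 20) and (10 vs 10 of 20)
mem = memory_pi(ConditioningTest(15, 5, 20), ConditioningTest(10, 10, 20))
print(f"memory PI = {mem}")  # positive = attraction to the sugar-paired odour

# a half with only 14 flies among the odorants is discarded
assert memory_pi(ConditioningTest(8, 6, 20), ConditioningTest(10, 10, 20)) is None

# locomotion: synthetic 25 fps tracks, walking 60 % of the time at 8 mm/s
traj, truth = make_trajectories(
    n_flies=2, duration_s=60, fps=25, bout_speeds=[(8.0, 0.6), (0.0, 0.4)], rng_seed=3
)
metrics = locomotion_metrics(traj)
print(metrics.to_string(index=False))
# walking_distance sums all frame displacements; walking_speed averages
# only frames above 4 mm/s; time_immobile counts frames below 1 mm/s.
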