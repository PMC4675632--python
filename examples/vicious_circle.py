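"""The vicious circle: expected punishment hands control to freezing.

With both controllers active, the red cue (fully avoidable) stays under
goal-directed control, while under the black cue the best action still
shocks 80% of the time: its Pavlovian value keeps falling, freezing is
triggered more often, freezing always shocks, and the value falls further.
"""

from aversim import run_sim2

result = run_sim2(n_seeds=5, n_trials=1000)
m = result.seed_mean()

print("P(goal-directed), 5-seed means:")
print(f"  red   cue, last quintile:  {m.p_gd_red_final:.3f}")
print(f"  black cue, first quintile: {m.p_gd_black_first:.3f}")
print(f"  black cue, last quintile:  {m.p_gd_black_final:.3f}")
print(f"  black cue Pavlovian value at the end: {m.pv_black_final:+.3f}")
print()
print("Goal-directed control survives where avoidance works (red) and decays")
print("where it mostly fails (black): the falling Pavlovian value recruits")
print("freezing, which guarantees shock and deepens the fall.")
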