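"""Learned helplessness via generalised controllability.

Two agents experience an uncontrollable context (90% shock whatever they
do): one for 500 trials, one for 7000.  Both are then moved to a novel,
controllable context (chain pulling avoids 90% of shocks) with all
context-bound knowledge reset — only the slow, context-free controllability
belief GC survives the switch.  The random streams of the test block are
yoked, so GC is the only difference between the pair.
"""

from aversim import run_sim4

result = run_sim4(n_seeds=5)
m = result.seed_mean()

print("generalised controllability at the end of uncontrollable training:")
print(f"  short (500 trials):  gc = {m.gc_end_block1_short:.3f}")
print(f"  long  (7000 trials): gc = {m.gc_end_block1_long:.3f}")
print("mean P(goal-directed) across the novel controllable block:")
print(f"  short-trained agent: {m.p_gd_block2_short:.3f}")
print(f"  long-trained agent:  {m.p_gd_block2_long:.3f}")
print()
print("Extended uncontrollable experience depletes the generalised belief,")
print("and the deficit carries into a context that is objectively")
print("controllable - the signature of learned helplessness.")
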