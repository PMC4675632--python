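"""Anatomy of one trial: every quantity the agent computes, in order.

Builds the avoidance task, runs a handful of trials, and prints the full
trace of the last one — the planning buffer, the chosen plan, the Pavlovian
reaction, the modulators, the instrumental-ability sum, and the outcome.
"""

from aversim import AgentState, default_config, load_task, run_trial
from aversim.agent import AGENT_ROLE, ENV_ROLE, block_rng

spec = load_task("sim2", n_trials=50)
config = default_config()
state = AgentState.fresh(spec, config)
env_rng = block_rng(config.seed, 0, ENV_ROLE)
agent_rng = block_rng(config.seed, 0, AGENT_ROLE)

for t in range(50):
    rec = run_trial(state, spec, t, env_rng, agent_rng)

print(f"trial {rec.trial_index}: cue = {rec.cue}")
print(f"  planning buffer q = { {a: round(v, 3) for a, v in rec.q.items()} }")
print(f"  plan: {rec.plan_action} (activation = best value = {rec.plan_activation:.3f})")
print(f"  Pavlovian reaction: {rec.pav_action} (value pv = {rec.pv:.3f})")
print(f"  modulators: sc = {rec.sc:.3f}  gc = {rec.gc:.3f}  tstd = {rec.tstd:.3f}")
print(f"  instrumental ability ia = {rec.ia:.3f} -> P(goal-directed) = {rec.p_goal_directed:.3f}")
print(f"  emitted by {rec.controller}: {rec.action} -> {rec.tone} (reinforcer {rec.reinforcer})")
print()
print("The buffer holds one expected value per action (sum of outcome")
print("probabilities times outcome values); sc is its spread; ia sums plan")
print("activation, controllability, Pavlovian value and threat distance, and")
print("its logistic decides which controller drives behaviour this trial.")
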