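# Threat distance: the cue-to-shock interval is signalled and varies
# randomly between 3 s and 30 s.  Contingencies follow the figure caption:
# red cue, lever pressing shocked 20% of the time; black cue, chain pulling
# shocked 40% of the time; every other action always leads to shock.
name: sim5
cues: [red, black]
actions: [lever_press, chain_pull, no_action]
outcomes: [high_tone, low_tone]
shock_value: -1.0
p_shock:
  red: {lever_press: 0.2, chain_pull: 1.0, no_action: 1.0}
  black: {lever_press: 1.0, chain_pull: 0.4, no_action: 1.0}
delay_levels: [3.0, 30.0]
blocks:
  - {cue: random, n_trials: 1000}
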