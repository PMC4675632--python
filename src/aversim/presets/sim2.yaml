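# Goal-directed / Pavlovian competition on the same contingencies as sim1:
# red fully avoidable by lever pressing, black 80% shock even with the best
# action.  The innate freezing response (no_action) always leads to shock,
# so on the black cue a vicious circle hands control to the Pavlovian side.
name: sim2
cues: [red, black]
actions: [lever_press, chain_pull, no_action]
outcomes: [high_tone, low_tone]
shock_value: -1.0
p_shock:
  red: {lever_press: 0.0, chain_pull: 1.0, no_action: 1.0}
  black: {lever_press: 1.0, chain_pull: 0.8, no_action: 1.0}
delay_levels: []
blocks:
  - {cue: random, n_trials: 1000}
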