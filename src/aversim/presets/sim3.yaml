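# Specific controllability: both cues carry the same best-case shock
# probability (0.8), but for red it is action-independent (uncontrollable)
# while for black only chain pulling achieves it (controllable).
name: sim3
cues: [red, black]
actions: [lever_press, chain_pull, no_action]
outcomes: [high_tone, low_tone]
shock_value: -1.0
p_shock:
  red: {lever_press: 0.8, chain_pull: 0.8, no_action: 0.8}
  black: {lever_press: 1.0, chain_pull: 0.8, no_action: 1.0}
delay_levels: []
blocks:
  - {cue: random, n_trials: 1000}
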