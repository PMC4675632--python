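# Learned helplessness: an uncontrollable first block (red cue, 90% shock
# regardless of action) followed by a controllable novel context (black cue,
# shock avoided 90% of the time by chain pulling, 10% otherwise).  This file
# describes the short-trained agent (500 block-1 trials); the long-trained
# variant (7000) is produced by replacing the first block's length.
name: sim4
cues: [red, black]
actions: [lever_press, chain_pull, no_action]
outcomes: [high_tone, low_tone]
shock_value: -1.0
p_shock:
  red: {lever_press: 0.9, chain_pull: 0.9, no_action: 0.9}
  black: {lever_press: 0.9, chain_pull: 0.1, no_action: 0.9}
delay_levels: []
blocks:
  - {cue: red, n_trials: 500}
  - {cue: black, n_trials: 500, novel_context: true}
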