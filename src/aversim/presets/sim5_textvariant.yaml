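# Variant of the threat-distance task in which lever pressing under the red
# cue always avoids shock (the running-text contingency rather than the
# figure caption's 20%).  Kept separate; the shipped default is sim5.yaml.
name: sim5_textvariant
cues: [red, black]
actions: [lever_press, chain_pull, no_action]
outcomes: [high_tone, low_tone]
shock_value: -1.0
p_shock:
  red: {lever_press: 0.0, chain_pull: 1.0, no_action: 1.0}
  black: {lever_press: 1.0, chain_pull: 0.4, no_action: 1.0}
delay_levels: [3.0, 30.0]
blocks:
  - {cue: random, n_trials: 1000}
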