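# aversim

Aversive behaviour emerges from two controllers pulling on the same motor
output: a **goal-directed** system that prospectively evaluates
stimulus → action → outcome contingencies, and a **Pavlovian** system that
attaches a learned value to each stimulus and answers it with a fixed innate
reaction (freezing, flight). `aversim` implements a computational model in
which the balance between the two is set trial-by-trial by *threat distance*
and by two levels of *controllability*, together with the simulated-rat
avoidance task used to probe it. It is written for computational
cognitive-neuroscience and computational-psychiatry researchers who want to
simulate avoidance learning, maladaptive freezing, and learned-helplessness
phenomena under explicit, reproducible assumptions.

## The model

On each trial a cue *c* is shown (optionally with a signalled delay to
threat), the agent emits one of three actions, and a tone plus (possibly) a
unit-magnitude shock follows.

**Goal-directed controller.** A Hebbian count table gives
P(o | c, a) = N(c,a,o) / Σ<sub>o'</sub> N(c,a,o'); outcome values v(o) are
learned by a terminal temporal-difference rule
v(o) ← v(o) + α<sub>v</sub>(r − v(o)). The planner fills a working-memory
buffer with q(a) = Σ<sub>o</sub> P(o|c,a) · v(o) and samples a plan from a
softmax with temperature τ. The plan node carries the *best* buffered value.

**Pavlovian controller.** Each cue holds a value
pv(c) ← pv(c) + α<sub>p</sub>(r − pv(c)) learned from the reinforcers
actually received in its presence; the response is innate and fixed, with
activation equal to pv(c).

**Modulators.** Specific controllability SC = max q − min q (the spread of
the buffer); generalised controllability GC follows SC across trials by a
slow delta rule, gc ← gc + α<sub>gc</sub>(sc − gc), and is the only quantity
that survives a context switch; threat distance TSTD = scale · delay.

**Arbitration.** The inputs are summed into an instrumental-ability scalar

IA = β + w<sub>gdp</sub>·q* + w<sub>sc</sub>·SC + w<sub>pr</sub>·pv +
w<sub>gc</sub>·GC + w<sub>tstd</sub>·TSTD

and the goal-directed plan is emitted with probability σ(IA) = 1/(1+e^(−IA)),
otherwise the innate reaction. All weights are non-negative; the Pavlovian
input is itself signed (≤ 0 under threat), so deeper expected punishment
lowers IA.

Five preset experiments (`sim1`–`sim5`, plus `sim5_textvariant`) exercise the
model: goal-directed learning alone, the vicious circle of Pavlovian
dominance, specific controllability at matched shock probability, learned
helplessness after 500 vs 7000 uncontrollable trials (yoked test blocks), and
threat-distance modulation at 3 s vs 30 s.

## Worked example

```bash
python examples/learned_helplessness.py
```

```
generalised controllability at the end of uncontrollable training:
  short (500 trials):  gc = 0.404
  long  (7000 trials): gc = 0.041
mean P(goal-directed) across the novel controllable block:
  short-trained agent: 0.905
  long-trained agent:  0.879
```

Both agents start with the same optimistic controllability belief
(gc = 0.5). Uncontrollable shock drives the observed action-value spread to
~0, so GC decays toward 0 — barely for the 500-trial agent (0.404), almost
completely for the 7000-trial agent (0.041). When both are dropped into a
novel, objectively controllable context with everything else reset, the
surviving GC difference translates into a persistent gap in goal-directed
engagement (0.905 vs 0.879 mean over the test block) — the model's account of
learned helplessness. The other examples
(`examples/goal_directed_learning.py`, `vicious_circle.py`,
`specific_controllability.py`, `threat_distance.py`,
`single_trial_anatomy.py`) each print one capability with a short
interpretation.

From Python:

```python
import aversim as av

result = av.run_sim2(n_seeds=20, n_trials=1000)
print(result.seed_mean())          # per-seed summary, seed-averaged
result.records.to_csv("trace.csv") # full per-trial trace
```

A thin CLI wraps the same runners:

```bash
aversim run sim3 --seeds 20 --out out/ --plot
aversim sweep sim2 --param temperature --values 0.05,0.1,0.25
```

## Layout

- `src/aversim/environment.py` — task, contingency tables, block schedule
- `src/aversim/goal_directed.py` — transition model, outcome values, planner
- `src/aversim/pavlovian.py` — stimulus values and innate reactions
- `src/aversim/modulators.py` — SC, GC, threat distance
- `src/aversim/arbitration.py` — instrumental ability and controller choice
- `src/aversim/agent.py` — trial loop, context resets, trace records
- `src/aversim/experiments.py` — the five preset experiments
- `src/aversim/presets/*.yaml` — task contingencies, editable
- `docs/methods.md` — modelling assumptions, defaults and their rationale
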