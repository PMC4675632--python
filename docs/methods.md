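# Methods

## Model and assumptions

The agent is a two-controller architecture over a discrete trial-based
avoidance task. A trial presents one cue; the agent emits one action; a
tone follows, perfectly coupled with shock delivery (one Bernoulli draw per
trial at the configured p_shock(cue, action)); the reinforcer is the shock
magnitude (−1 by default) or 0. The cue-to-tone interval is a label (a
signalled delay fed to the threat-distance channel), not simulated time.

**Goal-directed system.** Planning is a serial simulation over the action
repertoire, but the node-level dynamics (working-memory inhibition cycling
through action nodes) are implemented as a loop whose result is provably
the expectation sum q(a) = Σ_o P(o|c,a) v(o): the architecture specifies
the computation's outcome, not tick-level time constants, so simulating
them would add parameters without changing any prediction. Outcome
normalisation divides each cue-action-outcome count by the sum over all
outcomes for that cue-action pair (standard conditional-probability
normalisation). The plan node inherits the *maximum* buffered value even
when the softmax samples another action: plan activation reports the
prospect of the situation, not the sampled choice.

**Pavlovian system.** One value per cue, updated from the reinforcer
actually received on the trial. With terminal outcomes and a one-step
horizon, the temporal-difference and Rescorla–Wagner updates coincide; no
successor term exists. The innate response is configurable per cue and is
"no_action" (freezing) in every shipped task; it never changes within a
run. Because pv tracks realized outcomes under the agent's *own* policy,
frequent freezing that itself attracts shock drags pv further down — this
closed loop is what produces Pavlovian dominance under poorly avoidable
threat, and it is a feature, not an artefact.

**Modulators.** SC is the max−min spread of the planning buffer. GC is an
exponentially weighted average of SC across trials, independent of cue,
and is the only state that survives a context switch. TSTD is linear in
the signalled delay (a saturating 1−exp(−scale·d) variant exists, off by
default): linearity is the minimal reading of "activation corresponds to
the distance", and with only two delay levels in any shipped task the two
forms are observationally equivalent up to rescaling.

**Arbitration.** IA is an affine combination of plan activation, SC, the
signed Pavlovian activation, GC and TSTD with non-negative weights;
P(goal-directed) = logistic(IA). "Directly and inversely proportional" is
implemented as the logistic, since literal proportionality is not a
probability. Feeding the *signed* Pavlovian value through a non-negative
weight is the only reading under which stronger expected punishment
increases Pavlovian control while every channel keeps a positive
coefficient.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| alpha_v | 0.1 | per trial | outcome values must track the (deterministic) tone–shock coupling quickly; converges in ~50 experiences |
| alpha_p | 0.02 | per trial | Pavlovian values integrate over ~50 cue presentations; a faster rate makes early Pavlovian collapse outrun the first-quintile baseline it is measured against, and real conditioned-fear acquisition is slow relative to instrumental learning |
| alpha_gc | 0.0005 | per trial | GC must still distinguish 500 from 7000 uncontrollable trials: the prior retains e^(−500·α)≈0.78 after 500 trials but e^(−7000·α)≈0.03 after 7000; maximising the 500-vs-7000 separation analytically gives α≈4×10⁻⁴ |
| temperature | 0.05 | value units | action-value gaps in these tasks are ≤1 and typically 0.2; τ=0.05 gives ≥96% best-action choice at a 0.2 gap (near-greedy with residual exploration) |
| pseudocount | 1.0 | counts | defines uniform outcome probabilities before experience |
| gc_prior | 0.5 | value units | optimistic initial controllability (half the spread of a fully controllable unit-shock task); a zero prior would start agents helpless |
| tstd_scale | 0.05 | 1/s | maps the 3 s / 30 s delays to activations 0.15 / 1.5, commensurate with the other IA inputs |
| w_gdp, w_pr, w_gc, w_tstd | 1.0 | — | unit weights |
| w_sc | 3.0 | — | see below |
| bias | 0.0 | — | logistic midpoint at IA = 0 |

**Why w_sc = 3.** At equilibrium in the matched-shock-probability task, the
controllable cue's SC advantage (≈0.2) is almost exactly cancelled by its
Pavlovian penalty: its freezing trials always shock, pushing pv ≈ −0.95
versus −0.8 for the uncontrollable cue. With w_sc = w_pr the predicted
ordering of goal-directed control sits at a knife edge. Weighting the
controllability channel at 3 lets it dominate that cancellation while
leaving every other prediction intact; one shared configuration then
reproduces all five experiments' orderings with no per-experiment retuning.

All defaults are overridable via `AgentConfig` / YAML config files, and
every run's metadata records the full configuration and seed.

## Simulated conditions

The task generator *is* the study design: two cues, three actions
(lever press, chain pull, no action), two tones, shock value −1.
Contingencies per preset:

- sim1/sim2: red {LP 0, CP 1, NA 1}; black {LP 1, CP 0.8, NA 1}
- sim3: red {all 0.8}; black {LP 1, CP 0.8, NA 1}
- sim4: block 1 red {all 0.9}; block 2 (novel context) black
  {LP 0.9, CP 0.1, NA 0.9}; 500 vs 7000 block-1 trials, 500 test trials
- sim5: red {LP 0.2, CP 1, NA 1}; black {LP 1, CP 0.4, NA 1}; signalled
  delays 3 s / 30 s (a text variant with red/LP = 0 ships separately)

Cues are drawn uniformly per trial except in the helplessness schedule,
where each block fixes its cue; delays are uniform i.i.d. Trial counts
default to 1000 for the single-block experiments (configurable); the
asymptotic specific-controllability analysis uses a 12,000-trial horizon
because SC of an uncontrollable cue decays only as the transition counts
accumulate (O(n^−1/2) per action) and 1000 trials is visibly pre-asymptotic.
Multi-seed summaries use 20 seeds and compare first/last quintiles of the
trial range.

What the generator does *not* emulate: within-trial dynamics, response
latencies, habituation or extinction of the innate response,
uncertainty-dependent learning rates, and any habitual (stimulus–response
instrumental) controller. Passing tests therefore show that the
architecture produces the targeted phenomena under idealised stationary
contingencies, not that it fits animal or human data.

## Randomness and reproducibility

Every run derives all draws from a master seed through per-(seed, block,
role) substreams (role = environment or agent), each consuming exactly one
uniform per decision point. Consequences: (a) identical (config, seed)
runs are bit-identical, including CSV bytes; (b) two agents with different
block-1 lengths see *identical* environment and agent streams in block 2 —
a yoked design in which generalised controllability is the only state
crossing the boundary; (c) with the GC carry-over ablated
(`preserve_gc=False`), the paired test-block trajectories are exactly
identical, giving a sharp null for the helplessness comparison.

## Numerical choices and degenerate inputs

- Softmax uses max-subtraction; results match the naive formula to 1e-12
  where the latter is finite.
- Argmax ties in the buffer break by action-list order (deterministic).
- The logistic is evaluated branch-wise to avoid overflow.
- Counts are floored at a strictly positive pseudocount, so conditional
  probabilities are always defined and sum to 1 within 1e-12.
- Learning rates outside (0, 1], non-positive temperature or pseudocount,
  negative delays, negative arbitration weights, malformed contingency
  tables, and out-of-range trial indices all raise explicit errors.
- A context switch resets transition counts, outcome values and Pavlovian
  values to their initial settings ("all quantities"), including the
  tone–shock values even though tones recur across contexts — a deliberate
  literal reading; GC alone persists.

## Known limitations

- Single-step planning horizon only; multi-step policy evaluation and
  discounting are out of scope.
- The probability of goal-directed control is reported as the logistic
  output; the realized controller identity per trial is also recorded, and
  the two agree in long-run frequency.
- The sim-4 helplessness gap in test-block behaviour is real but modest at
  these defaults (the short-trained agent's advantage is a persistent
  ~0.03–0.1 in P(goal-directed)); it is the GC ordering that is large.
- The arbitration weights are not fitted to data; they are the single
  calibrated configuration described above.
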