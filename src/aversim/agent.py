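"""Trial-by-trial agent runtime.

One trial runs, in order: perceive the stimulus, fill the planning buffer,
softmax-select a plan, retrieve the Pavlovian reaction, compute the
modulators (specific controllability from the buffer, threat-distance
activation from the signalled delay), sum everything into instrumental
ability, sample which controller emits behaviour, resolve the outcome in
the environment, and only then learn (transition counts, outcome value,
Pavlovian value, generalised controllability).  All decisions use the
pre-update state: there is no within-trial leakage of this trial's outcome
into this trial's choices.

Randomness: each (seed, block, role) triple gets its own deterministic
substream, role 0 for the environment and role 1 for the agent.  Two runs
that share a seed and block index therefore see identical draws for that
block even if their earlier blocks differ in length — the yoking needed to
compare short- and long-trained agents on a common test block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .arbitration import ArbitrationParams, compute_ia, select_behaviour
from .environment import TaskSpec, environment_step, present_stimulus
from .goal_directed import (
    OutcomeValueTable,
    TransitionModel,
    choose_plan,
    plan_values,
    update_outcome_value,
    update_transition,
)
from .modulators import ModulatorState, compute_sc, compute_tstd, update_gc
from .pavlovian import PavlovianState, pavlovian_react, update_pv

__all__ = [
    "AgentConfig",
    "AgentState",
    "TrialRecord",
    "run_trial",
    "run_task",
    "context_switch_reset",
    "records_to_frame",
    "block_rng",
]

ENV_ROLE, AGENT_ROLE = 0, 1


@dataclass(frozen=True)
class AgentConfig:
    """All tunable agent parameters.

    alpha_v, alpha_p
        Learning rates for outcome values and Pavlovian values.
    alpha_gc
        Learning rate of generalised controllability; much slower than the
        value rates so that controllability beliefs integrate over long
        histories.
    temperature
        Softmax temperature of goal-directed plan selection.
    pseudocount
        Prior count per cue-action-outcome triple of the transition model.
    gc_prior
        Initial (optimistic) generalised-controllability belief.
    tstd_scale
        Seconds-to-activation conversion of the threat-distance channel.
    innate_response
        Action id (or cue -> action map) of the fixed Pavlovian reaction.
    """

    alpha_v: float = 0.1
    alpha_p: float = 0.02
    alpha_gc: float = 0.0005
    temperature: float = 0.05
    pseudocount: float = 1.0
    gc_prior: float = 0.5
    tstd_scale: float = 0.05
    saturating_tstd: bool = False
    innate_response: str | dict = "no_action"
    arbitration: ArbitrationParams = field(default_factory=ArbitrationParams)
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_v", "alpha_p", "alpha_gc"):
            rate = getattr(self, name)
            if not (0 < rate <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {rate}")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")
        if isinstance(self.arbitration, dict):
            object.__setattr__(self, "arbitration", ArbitrationParams(**self.arbitration))

    def replace(self, **kw) -> "AgentConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AgentConfig":
        d = dict(d)
        if "arbitration" in d and isinstance(d["arbitration"], dict):
            d["arbitration"] = ArbitrationParams(**d["arbitration"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AgentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class AgentState:
    """Mutable learning state of one agent bound to one task."""

    model: TransitionModel
    values: OutcomeValueTable
    pav: PavlovianState
    mod: ModulatorState
    config: AgentConfig

    @classmethod
    def fresh(cls, spec: TaskSpec, config: AgentConfig | None = None) -> "AgentState":
        config = config or AgentConfig()
        return cls(
            model=TransitionModel.uniform(
                spec.cues, spec.actions, spec.outcomes, config.pseudocount
            ),
            values=OutcomeValueTable.zeros(spec.outcomes),
            pav=PavlovianState.fresh(spec.cues, config.innate_response),
            mod=ModulatorState(
                gc=config.gc_prior,
                alpha_gc=config.alpha_gc,
                tstd_scale=config.tstd_scale,
                saturating_tstd=config.saturating_tstd,
            ),
            config=config,
        )


@dataclass(frozen=True)
class TrialRecord:
    """Complete per-trial trace (pre-decision quantities plus post-update
    values); the raw material of every summary statistic."""

    trial_index: int
    block: int
    cue: str
    delay_s: float | None
    q: dict[str, float]
    plan_action: str
    plan_activation: float
    pav_action: str
    pv: float
    sc: float
    gc: float
    tstd: float
    ia: float
    p_goal_directed: float
    controller: str
    action: str
    tone: str
    shock: bool
    reinforcer: float
    pv_post: float
    gc_post: float
    v_post: dict[str, float]


def run_trial(
    state: AgentState,
    spec: TaskSpec,
    trial_index: int,
    env_rng: np.random.Generator,
    agent_rng: np.random.Generator,
) -> TrialRecord:
    """Execute one full trial and learn from its outcome.

    The state is mutated in place; the returned record captures the
    decision variables as they were *before* learning, plus the post-update
    values.
    """
    cfg = state.config
    block_index, _ = spec.block_at(trial_index)

    # -- perceive and decide (pre-update state only) ------------------
    stimulus = present_stimulus(spec, trial_index, env_rng)
    buffer = plan_values(state.model, state.values, stimulus.cue)
    plan = choose_plan(buffer, cfg.temperature, agent_rng)
    pav_action, pr_activation = pavlovian_react(state.pav, stimulus.cue)
    sc = compute_sc(buffer)
    tstd = (
        compute_tstd(stimulus.delay_s, cfg.tstd_scale, cfg.saturating_tstd)
        if stimulus.delay_s is not None
        else 0.0
    )
    ia = compute_ia(
        plan.activation, sc, pr_activation, state.mod.gc, tstd, cfg.arbitration
    )
    decision = select_behaviour(ia, plan, pav_action, cfg.arbitration, agent_rng)

    # -- act ----------------------------------------------------------
    outcome = environment_step(spec, stimulus, decision.emitted_action, env_rng)

    gc_pre = state.mod.gc
    # -- learn --------------------------------------------------------
    update_transition(state.model, stimulus.cue, decision.emitted_action, outcome.tone)
    update_outcome_value(state.values, outcome.tone, outcome.reinforcer, cfg.alpha_v)
    update_pv(state.pav, stimulus.cue, outcome.reinforcer, cfg.alpha_p)
    state.mod.sc = sc
    state.mod.tstd = tstd
    update_gc(state.mod, sc)

    return TrialRecord(
        trial_index=trial_index,
        block=block_index,
        cue=stimulus.cue,
        delay_s=stimulus.delay_s,
        q=dict(buffer.q),
        plan_action=plan.action,
        plan_activation=plan.activation,
        pav_action=pav_action,
        pv=pr_activation,
        sc=sc,
        gc=gc_pre,
        tstd=tstd,
        ia=ia,
        p_goal_directed=decision.p_goal_directed,
        controller=decision.controller,
        action=decision.emitted_action,
        tone=outcome.tone,
        shock=outcome.shock,
        reinforcer=outcome.reinforcer,
        pv_post=state.pav.pv[stimulus.cue],
        gc_post=state.mod.gc,
        v_post=dict(state.values.v),
    )


def context_switch_reset(state: AgentState, preserve_gc: bool = True) -> AgentState:
    """Reset all context-bound quantities at a novel-context boundary.

    Transition counts, outcome values and Pavlovian values return to their
    initial settings; generalised controllability survives unless
    ``preserve_gc`` is false, in which case the reset is a full rebirth.
    Idempotent.
    """
    cfg = state.config
    for key in state.model.counts:
        state.model.counts[key] = cfg.pseudocount
    for o in state.values.v:
        state.values.v[o] = 0.0
    for c in state.pav.pv:
        state.pav.pv[c] = 0.0
    state.mod.sc = 0.0
    state.mod.tstd = 0.0
    if not preserve_gc:
        state.mod.gc = cfg.gc_prior
    return state


def block_rng(seed: int, block_index: int, role: int) -> np.random.Generator:
    """Deterministic substream for one (seed, block, role) triple."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(block_index, role))
    )


def run_task(
    spec: TaskSpec,
    config: AgentConfig | None = None,
    seed: int | None = None,
    preserve_gc: bool = True,
) -> tuple[AgentState, list[TrialRecord]]:
    """Run an agent through the full block structure of a task.

    Returns the final state and the complete trial trace.  ``seed``
    defaults to ``config.seed``.  Blocks flagged ``novel_context`` trigger
    a context reset (GC preserved unless ``preserve_gc`` is false).
    """
    config = config or AgentConfig()
    if seed is None:
        seed = config.seed
    state = AgentState.fresh(spec, config)
    records: list[TrialRecord] = []
    t = 0
    for b_idx, block in enumerate(spec.blocks):
        if block.novel_context and t > 0:
            context_switch_reset(state, preserve_gc=preserve_gc)
        env_rng = block_rng(seed, b_idx, ENV_ROLE)
        agent_rng = block_rng(seed, b_idx, AGENT_ROLE)
        for _ in range(block.n_trials):
            records.append(run_trial(state, spec, t, env_rng, agent_rng))
            t += 1
    return state, records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records into a tidy DataFrame (one row per trial).

    Per-action values become ``q_<action>`` columns and post-update outcome
    values ``v_<outcome>`` columns; the column set is stable for a given
    task.
    """
    rows = []
    for r in records:
        row = {
            "trial_index": r.trial_index,
            "block": r.block,
            "cue": r.cue,
            "delay_s": r.delay_s,
            "plan_action": r.plan_action,
            "plan_activation": r.plan_activation,
            "pav_action": r.pav_action,
            "pv": r.pv,
            "sc": r.sc,
            "gc": r.gc,
            "tstd": r.tstd,
            "ia": r.ia,
            "p_goal_directed": r.p_goal_directed,
            "controller": r.controller,
            "action": r.action,
            "tone": r.tone,
            "shock": r.shock,
            "reinforcer": r.reinforcer,
            "pv_post": r.pv_post,
            "gc_post": r.gc_post,
        }
        for a, v in r.q.items():
            row[f"q_{a}"] = v
        for o, v in r.v_post.items():
            row[f"v_{o}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
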