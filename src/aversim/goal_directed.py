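"""Goal-directed (prospective) controller.

The goal-directed subsystem evaluates each candidate action for the current
cue by mentally simulating its likely outcomes: a learned transition model
supplies P(outcome | cue, action), a learned outcome-value table supplies
the worth of each outcome, and the expected value of the action is the
probability-weighted sum.  The per-action values are held in a working-memory
buffer; a softmax over the buffer selects the plan.  The plan node carries
the activation of the *best* buffer entry even when softmax picks another
action — plan activation reports how good the situation could be, not what
was sampled.

Learning is Hebbian for the transition model (the experienced
cue-action-outcome triple accumulates count mass on top of a pseudocount
prior) and a terminal temporal-difference delta rule for outcome values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransitionModel",
    "OutcomeValueTable",
    "ActionValueBuffer",
    "GoalDirectedPlan",
    "plan_values",
    "choose_plan",
    "update_transition",
    "update_outcome_value",
]


@dataclass
class TransitionModel:
    """Hebbian cue-action-outcome counts and the conditional probabilities
    they induce.

    Counts start at a strictly positive pseudocount per triple so that
    P(outcome | cue, action) is defined (and uniform) before any experience,
    and they only ever grow, so probabilities are always normalised.
    """

    cues: tuple[str, ...]
    actions: tuple[str, ...]
    outcomes: tuple[str, ...]
    counts: dict[tuple[str, str, str], float]
    pseudocount: float = 1.0

    @classmethod
    def uniform(cls, cues, actions, outcomes, pseudocount: float = 1.0):
        """Model with every triple at the pseudocount (uniform prior)."""
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        cues, actions, outcomes = tuple(cues), tuple(actions), tuple(outcomes)
        counts = {
            (c, a, o): float(pseudocount)
            for c in cues
            for a in actions
            for o in outcomes
        }
        return cls(cues, actions, outcomes, counts, float(pseudocount))

    def prob(self, cue: str, action: str, outcome: str) -> float:
        """P(outcome | cue, action) = count / sum of counts over outcomes."""
        total = sum(self.counts[(cue, action, o)] for o in self.outcomes)
        return self.counts[(cue, action, outcome)] / total

    def outcome_probs(self, cue: str, action: str) -> dict[str, float]:
        total = sum(self.counts[(cue, action, o)] for o in self.outcomes)
        return {o: self.counts[(cue, action, o)] / total for o in self.outcomes}


@dataclass
class OutcomeValueTable:
    """Expected value of each outcome (tone), learned by a delta rule."""

    v: dict[str, float]

    @classmethod
    def zeros(cls, outcomes):
        return cls({o: 0.0 for o in outcomes})


@dataclass
class ActionValueBuffer:
    """Working-memory buffer: one expected value per action for the current
    cue.  ``best_action`` breaks exact ties by action-list order."""

    q: dict[str, float]
    best_action: str
    best_value: float


@dataclass
class GoalDirectedPlan:
    """Softmax-selected plan.  ``activation`` is the buffer maximum, which
    may exceed the chosen action's own value."""

    action: str
    activation: float
    choice_probs: dict[str, float]


def plan_values(
    model: TransitionModel, values: OutcomeValueTable, cue: str
) -> ActionValueBuffer:
    """Fill the working-memory buffer with one expected value per action.

    Implements the serial simulate-then-inhibit planning cycle as a loop:
    each action is simulated in repertoire order and its expected value
    q(a) = sum_o P(o | cue, a) * v(o) is written to the buffer.
    """
    if cue not in model.cues:
        raise ValueError(f"unknown cue {cue!r}; expected one of {model.cues}")
    q: dict[str, float] = {}
    best_action = None
    best_value = -math.inf
    for action in model.actions:  # serial action simulation
        total = sum(model.counts[(cue, action, o)] for o in model.outcomes)
        ev = sum(
            model.counts[(cue, action, o)] / total * values.v[o]
            for o in model.outcomes
        )
        q[action] = ev
        if ev > best_value:  # strict: ties keep the earlier action
            best_value = ev
            best_action = action
    return ActionValueBuffer(q=q, best_action=best_action, best_value=best_value)


def choose_plan(
    buffer: ActionValueBuffer, temperature: float, rng: np.random.Generator
) -> GoalDirectedPlan:
    """Sample a plan from the softmax over buffered action values.

    Uses max-subtraction for numerical stability; identical to the naive
    softmax up to floating-point rounding.  Consumes exactly one uniform
    draw from ``rng``.
    """
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    actions = list(buffer.q)
    m = max(buffer.q.values())
    weights = [math.exp((buffer.q[a] - m) / temperature) for a in actions]
    z = sum(weights)
    probs = [w / z for w in weights]
    u = rng.random()
    acc = 0.0
    chosen = actions[-1]
    for a, p in zip(actions, probs):
        acc += p
        if u < acc:
            chosen = a
            break
    return GoalDirectedPlan(
        action=chosen,
        activation=buffer.best_value,
        choice_probs=dict(zip(actions, probs)),
    )


def update_transition(
    model: TransitionModel,
    cue: str,
    action: str,
    tone: str,
    increment: float = 1.0,
) -> TransitionModel:
    """Hebbian strengthening of the experienced cue-action-outcome triple.

    Only the executed action's row changes; the derived conditional
    probabilities renormalise automatically.  The model is updated in place
    and returned for chaining.
    """
    if cue not in model.cues:
        raise ValueError(f"unknown cue {cue!r}")
    if action not in model.actions:
        raise ValueError(f"unknown action {action!r}")
    if tone not in model.outcomes:
        raise ValueError(f"unknown outcome {tone!r}")
    if increment <= 0:
        raise ValueError("increment must be positive")
    model.counts[(cue, action, tone)] += increment
    return model


def update_outcome_value(
    values: OutcomeValueTable, tone: str, reinforcer: float, alpha_v: float
) -> OutcomeValueTable:
    """Terminal TD update of the experienced outcome's value.

    v(tone) += alpha_v * (reinforcer - v(tone)).  With a one-step horizon
    and terminal outcomes there is no bootstrapped successor term, so this
    coincides with the Rescorla-Wagner delta rule.
    """
    if not (0 < alpha_v <= 1):
        raise ValueError(f"alpha_v must be in (0, 1], got {alpha_v}")
    if tone not in values.v:
        raise ValueError(f"unknown outcome {tone!r}")
    values.v[tone] += alpha_v * (reinforcer - values.v[tone])
    return values
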