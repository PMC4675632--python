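"""Arbitration between goal-directed and Pavlovian control.

The subsystem outputs are summed into a single Instrumental Ability scalar

    IA = bias + w_gdp * plan_activation + w_sc * sc + w_pr * pr_activation
             + w_gc * gc + w_tstd * tstd

and the probability that the emitted behaviour is the goal-directed plan
(rather than the innate Pavlovian reaction) is the logistic of IA.  All
weights are non-negative; the Pavlovian-response input is itself signed
(it equals the cue's Pavlovian value, <= 0 under threat), so a stronger
expected punishment lowers IA and hands control to the Pavlovian system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .goal_directed import GoalDirectedPlan

__all__ = [
    "ArbitrationParams",
    "BehaviourDecision",
    "compute_ia",
    "logistic",
    "select_behaviour",
]


@dataclass(frozen=True)
class ArbitrationParams:
    """Weights and intercept of the instrumental-ability sum.

    ``gd_only`` disables the competition entirely: behaviour is always the
    goal-directed plan (IA and its logistic are still computed and
    recorded).
    """

    w_gdp: float = 1.0
    w_sc: float = 3.0
    w_pr: float = 1.0
    w_gc: float = 1.0
    w_tstd: float = 1.0
    bias: float = 0.0
    gd_only: bool = False

    def __post_init__(self):
        for name in ("w_gdp", "w_sc", "w_pr", "w_gc", "w_tstd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BehaviourDecision:
    """Outcome of the controller competition on one trial."""

    ia: float
    p_goal_directed: float
    emitted_action: str
    controller: str  # "goal_directed" | "pavlovian"


def compute_ia(
    plan_activation: float,
    sc: float,
    pr_activation: float,
    gc: float,
    tstd: float,
    params: ArbitrationParams,
) -> float:
    """Weighted sum of the five controller/modulator inputs plus bias."""
    return (
        params.bias
        + params.w_gdp * plan_activation
        + params.w_sc * sc
        + params.w_pr * pr_activation
        + params.w_gc * gc
        + params.w_tstd * tstd
    )


def logistic(x: float) -> float:
    """Numerically safe 1 / (1 + exp(-x))."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def select_behaviour(
    ia: float,
    plan: GoalDirectedPlan,
    pav_action: str,
    params: ArbitrationParams,
    rng: np.random.Generator,
) -> BehaviourDecision:
    """Emit the plan with probability logistic(IA), else the innate reaction.

    Consumes exactly one uniform draw from ``rng`` regardless of mode, so
    random streams stay aligned between gd_only and competitive runs.
    """
    p = logistic(ia)
    u = rng.random()
    if params.gd_only or u < p:
        controller, action = "goal_directed", plan.action
    else:
        controller, action = "pavlovian", pav_action
    return BehaviourDecision(
        ia=ia, p_goal_directed=p, emitted_action=action, controller=controller
    )
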