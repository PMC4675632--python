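"""Modulatory signals: controllability and threat distance.

Specific controllability (SC) is the spread — max minus min — of the
working-memory action values for the current cue: when one action is much
better than the alternatives the situation is controllable; when all
actions are equivalent it is not.

Generalised controllability (GC) is a slow, cue-independent delta-rule
average of the SC values experienced across trials.  It persists through
context switches, which is what lets a long history of uncontrollable
punishment suppress instrumental engagement in a brand-new context
(learned helplessness).

Threat-distance activation (TSTD) converts the signalled time (or space)
to threat into a scalar; by default linearly, optionally with a saturating
1 - exp(-scale * d) form.  Larger distance means more room for deliberate,
goal-directed control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .goal_directed import ActionValueBuffer

__all__ = ["ModulatorState", "compute_sc", "update_gc", "compute_tstd"]


@dataclass
class ModulatorState:
    """Current modulator activations and their parameters.

    ``sc`` and ``tstd`` are per-trial quantities refreshed by the runtime;
    ``gc`` is the only field with cross-trial (and cross-context) memory.
    """

    gc: float
    alpha_gc: float
    tstd_scale: float = 0.05
    sc: float = 0.0
    tstd: float = 0.0
    saturating_tstd: bool = False

    def __post_init__(self):
        if not (0 < self.alpha_gc <= 1):
            raise ValueError(f"alpha_gc must be in (0, 1], got {self.alpha_gc}")
        if not self.tstd_scale > 0:
            raise ValueError("tstd_scale must be positive")


def compute_sc(buffer: ActionValueBuffer) -> float:
    """Specific controllability: max minus min of the buffered action values."""
    if not buffer.q:
        raise ValueError("cannot compute controllability of an empty buffer")
    vals = buffer.q.values()
    return max(vals) - min(vals)


def update_gc(state: ModulatorState, sc_observed: float) -> ModulatorState:
    """Delta-rule update of generalised controllability from this trial's SC.

    gc += alpha_gc * (sc - gc): an exponentially weighted average of the SC
    history, independent of which cue was present.  Updated in place and
    returned.
    """
    state.gc += state.alpha_gc * (sc_observed - state.gc)
    return state


def compute_tstd(
    delay_s: float, scale: float, saturating: bool = False
) -> float:
    """Threat-distance activation for a signalled delay.

    Linear by default (``scale * delay_s``); the saturating variant
    ``1 - exp(-scale * delay_s)`` is available but off by default.  A trial
    with no signalled delay should pass 0.
    """
    if delay_s < 0:
        raise ValueError(f"delay must be non-negative, got {delay_s}")
    if not scale > 0:
        raise ValueError("scale must be positive")
    if saturating:
        return 1.0 - math.exp(-scale * delay_s)
    return scale * delay_s
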