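"""Pavlovian (reactive) controller.

Each cue carries a learned Pavlovian value — the exponentially weighted
average of the reinforcers actually experienced in its presence, regardless
of which action produced them.  The controller's response to a cue is fixed
and innate (freezing, modelled as "no_action", in all shipped tasks); only
its vigor changes, tracking the cue's value with unit proportionality.

Because the Pavlovian value follows the reinforcers received under the
agent's *own* behaviour, a freezing response that itself attracts shocks
drives the value further down — the self-sustaining loop behind maladaptive
avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PavlovianState", "pavlovian_react", "update_pv"]


@dataclass
class PavlovianState:
    """Per-cue Pavlovian values and the fixed innate response map."""

    pv: dict[str, float]
    innate_response: dict[str, str]

    @classmethod
    def fresh(cls, cues, innate_response: str | dict = "no_action"):
        """Neutral state: all values 0; one innate response per cue.

        ``innate_response`` may be a single action id (used for every cue)
        or a full cue -> action map.
        """
        cues = tuple(cues)
        if isinstance(innate_response, str):
            innate = {c: innate_response for c in cues}
        else:
            innate = dict(innate_response)
            missing = [c for c in cues if c not in innate]
            if missing:
                raise ValueError(f"innate_response missing cues {missing}")
        return cls(pv={c: 0.0 for c in cues}, innate_response=innate)


def pavlovian_react(state: PavlovianState, cue: str) -> tuple[str, float]:
    """Return the innate response and its activation (= the cue's value)."""
    if cue not in state.pv:
        raise ValueError(f"unknown cue {cue!r}; expected one of {tuple(state.pv)}")
    return state.innate_response[cue], state.pv[cue]


def update_pv(
    state: PavlovianState, cue: str, reinforcer: float, alpha_p: float
) -> PavlovianState:
    """Delta-rule update of the presented cue's Pavlovian value.

    pv(cue) += alpha_p * (reinforcer - pv(cue)); other cues untouched.
    The fixed point under a stationary behavioural policy is minus the
    realized shock frequency times the shock magnitude.
    """
    if not (0 < alpha_p <= 1):
        raise ValueError(f"alpha_p must be in (0, 1], got {alpha_p}")
    if cue not in state.pv:
        raise ValueError(f"unknown cue {cue!r}")
    state.pv[cue] += alpha_p * (reinforcer - state.pv[cue])
    return state
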