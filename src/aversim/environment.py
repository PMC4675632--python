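"""Simulated-rat avoidance task.

On each trial a visual cue appears (optionally with a signalled delay to
threat), the agent performs one action, and the environment returns an
auditory tone plus shock according to a cue-action contingency table: the
high tone is perfectly coupled with shock delivery, the low tone with shock
omission.  One Bernoulli draw per trial decides the tone; the reinforcer is
``shock_value`` (negative) on shock trials and 0 otherwise.

The task is organised into blocks.  A block either fixes the cue (as in the
learned-helplessness schedule, where one context is presented for a whole
block) or draws it uniformly per trial.  Blocks flagged ``novel_context``
mark points where the agent should treat the environment as new.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Block",
    "TaskSpec",
    "TrialStimulus",
    "TrialOutcome",
    "present_stimulus",
    "environment_step",
]

#: sentinel cue rule meaning "draw uniformly among the spec's cues"
RANDOM_CUE = "random"


@dataclass(frozen=True)
class Block:
    """A contiguous run of trials with a fixed cue-presentation rule.

    ``cue`` is either a cue identifier or :data:`RANDOM_CUE`.  When
    ``novel_context`` is true the agent is expected to reset its
    context-bound state at the block boundary (generalised controllability
    survives the switch).
    """

    cue: str
    n_trials: int
    novel_context: bool = False


@dataclass(frozen=True)
class TaskSpec:
    """Contingency table and block structure of an avoidance task.

    Parameters
    ----------
    cues, actions
        Identifiers of the visual cues and of the available actions.
    outcomes
        Ordered pair ``(shock_tone, safe_tone)``: the first tone is always
        followed by shock, the second never.
    p_shock
        Map ``(cue, action) -> probability`` of the shock tone.  Every
        (cue, action) pair must be present.
    shock_value
        Reinforcer magnitude on shock trials; must be negative.  The safe
        outcome is worth 0.
    delay_levels
        Signalled cue-to-threat delays in seconds, sampled uniformly per
        trial.  Empty when threat distance is not manipulated.
    blocks
        Ordered block structure; the total trial budget is their sum.
    """

    cues: tuple[str, ...]
    actions: tuple[str, ...]
    outcomes: tuple[str, str]
    p_shock: dict[tuple[str, str], float]
    shock_value: float = -1.0
    delay_levels: tuple[float, ...] = ()
    blocks: tuple[Block, ...] = ()
    name: str = "task"

    def __post_init__(self):
        object.__setattr__(self, "cues", tuple(self.cues))
        object.__setattr__(self, "actions", tuple(self.actions))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        object.__setattr__(self, "delay_levels", tuple(self.delay_levels))
        object.__setattr__(
            self,
            "blocks",
            tuple(b if isinstance(b, Block) else Block(**b) for b in self.blocks),
        )
        if len(self.outcomes) != 2:
            raise ValueError("exactly two outcomes (shock tone, safe tone) required")
        if not self.shock_value < 0:
            raise ValueError("shock_value must be negative (aversive by construction)")
        for cue in self.cues:
            for action in self.actions:
                if (cue, action) not in self.p_shock:
                    raise ValueError(f"p_shock missing entry for {(cue, action)}")
        for pair, p in self.p_shock.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p_shock{pair} = {p} outside [0, 1]")
        if any(d < 0 for d in self.delay_levels):
            raise ValueError("delay levels must be non-negative seconds")
        for b in self.blocks:
            if b.cue != RANDOM_CUE and b.cue not in self.cues:
                raise ValueError(f"block cue {b.cue!r} not among task cues")
            if b.n_trials <= 0:
                raise ValueError("block n_trials must be positive")

    @property
    def shock_tone(self) -> str:
        return self.outcomes[0]

    @property
    def safe_tone(self) -> str:
        return self.outcomes[1]

    @property
    def n_trials(self) -> int:
        """Total trial budget over all blocks."""
        return sum(b.n_trials for b in self.blocks)

    def block_at(self, trial_index: int) -> tuple[int, Block]:
        """Return (block index, block) active at a global trial index."""
        if trial_index < 0:
            raise IndexError(f"trial_index {trial_index} is negative")
        offset = trial_index
        for i, b in enumerate(self.blocks):
            if offset < b.n_trials:
                return i, b
            offset -= b.n_trials
        raise IndexError(
            f"trial_index {trial_index} outside trial budget {self.n_trials}"
        )

    def with_blocks(self, blocks) -> "TaskSpec":
        """Copy of this spec with a replaced block structure."""
        d = self.to_dict()
        d["blocks"] = [asdict(b) if isinstance(b, Block) else dict(b) for b in blocks]
        return TaskSpec.from_dict(d)

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cues": list(self.cues),
            "actions": list(self.actions),
            "outcomes": list(self.outcomes),
            "shock_value": self.shock_value,
            "p_shock": {
                cue: {a: float(self.p_shock[(cue, a)]) for a in self.actions}
                for cue in self.cues
            },
            "delay_levels": list(self.delay_levels),
            "blocks": [asdict(b) for b in self.blocks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TaskSpec":
        p_shock = {
            (cue, a): float(p)
            for cue, row in d["p_shock"].items()
            for a, p in row.items()
        }
        return cls(
            cues=tuple(d["cues"]),
            actions=tuple(d["actions"]),
            outcomes=tuple(d["outcomes"]),
            p_shock=p_shock,
            shock_value=float(d.get("shock_value", -1.0)),
            delay_levels=tuple(d.get("delay_levels", ())),
            blocks=tuple(Block(**b) for b in d.get("blocks", ())),
            name=d.get("name", "task"),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "TaskSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class TrialStimulus:
    """What the agent perceives at trial onset: cue and signalled delay."""

    cue: str
    trial_index: int
    delay_s: float | None = None


@dataclass(frozen=True)
class TrialOutcome:
    """Tone, shock flag and reinforcer delivered at the end of a trial."""

    tone: str
    shock: bool
    reinforcer: float


def present_stimulus(
    spec: TaskSpec, trial_index: int, rng: np.random.Generator
) -> TrialStimulus:
    """Present the cue (and signalled delay) for a given trial.

    The cue is dictated by the active block: fixed for single-cue blocks,
    drawn uniformly for :data:`RANDOM_CUE` blocks.  When the task manipulates
    threat distance, one of ``delay_levels`` is drawn uniformly.
    """
    _, block = spec.block_at(trial_index)
    if block.cue == RANDOM_CUE:
        cue = spec.cues[int(rng.random() * len(spec.cues))]
    else:
        cue = block.cue
    delay = None
    if spec.delay_levels:
        delay = spec.delay_levels[int(rng.random() * len(spec.delay_levels))]
    return TrialStimulus(cue=cue, trial_index=trial_index, delay_s=delay)


def environment_step(
    spec: TaskSpec,
    stimulus: TrialStimulus,
    action: str,
    rng: np.random.Generator,
) -> TrialOutcome:
    """Resolve one trial: draw the tone and deliver the reinforcer.

    The shock tone is emitted with probability ``p_shock(cue, action)``;
    tone and shock are perfectly coupled (a single Bernoulli draw).
    """
    if action not in spec.actions:
        raise ValueError(f"unknown action {action!r}; expected one of {spec.actions}")
    try:
        p = spec.p_shock[(stimulus.cue, action)]
    except KeyError:
        raise ValueError(
            f"no contingency for cue/action pair {(stimulus.cue, action)}"
        ) from None
    shock = rng.random() < p
    tone = spec.shock_tone if shock else spec.safe_tone
    return TrialOutcome(
        tone=tone, shock=shock, reinforcer=spec.shock_value if shock else 0.0
    )
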