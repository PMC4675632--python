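import numpy as np
import pytest

from aversim import AgentConfig, Block, TaskSpec


@pytest.fixture
def two_cue_spec() -> TaskSpec:
    """Small task with one fully avoidable and one poorly avoidable cue."""
    return TaskSpec(
        cues=("red", "black"),
        actions=("lever_press", "chain_pull", "no_action"),
        outcomes=("high_tone", "low_tone"),
        p_shock={
            ("red", "lever_press"): 0.0,
            ("red", "chain_pull"): 1.0,
            ("red", "no_action"): 1.0,
            ("black", "lever_press"): 1.0,
            ("black", "chain_pull"): 0.8,
            ("black", "no_action"): 1.0,
        },
        blocks=(Block("random", 200),),
        name="fixture",
    )


@pytest.fixture
def config() -> AgentConfig:
    return AgentConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)
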