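"""Goal-directed controller: planning buffer, softmax choice, learning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aversim import (
    ActionValueBuffer,
    OutcomeValueTable,
    TransitionModel,
    choose_plan,
    plan_values,
    update_outcome_value,
    update_transition,
)

CUES = ("c0",)
OUTCOMES = ("high_tone", "low_tone")


def brute_force_expectations(model, values, cue):
    """Independent oracle: explicit enumeration of sum_o P(o|c,a) v(o)
    from the raw counts, one term at a time."""
    out = {}
    for a in model.actions:
        total = 0.0
        for o in model.outcomes:
            total += model.counts[(cue, a, o)]
        ev = 0.0
        for o in model.outcomes:
            ev += (model.counts[(cue, a, o)] / total) * values.v[o]
        out[a] = ev
    return out


def model_with_probs(p_by_action, pseudoscale=1000.0):
    """Transition model whose conditional shock-tone probabilities are the
    given exact values (counts chosen proportionally)."""
    actions = tuple(p_by_action)
    model = TransitionModel.uniform(CUES, actions, OUTCOMES)
    for a, p in p_by_action.items():
        model.counts[(CUES[0], a, "high_tone")] = p * pseudoscale
        model.counts[(CUES[0], a, "low_tone")] = (1 - p) * pseudoscale + 1e-9
    return model


def test_plan_values_examples():
    """Zero shock probability gives value 0; probability 0.8 on a -1 shock
    gives -0.8 (hand-arithmetic expectation)."""
    values = OutcomeValueTable({"high_tone": -1.0, "low_tone": 0.0})
    model = model_with_probs({"LP": 0.0, "CP": 0.8})
    buf = plan_values(model, values, "c0")
    assert buf.q["LP"] == pytest.approx(0.0, abs=1e-9)
    assert buf.q["CP"] == pytest.approx(-0.8, abs=1e-9)
    assert buf.best_action == "LP"
    assert buf.best_value == pytest.approx(0.0, abs=1e-9)


def test_plan_values_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(1234)
    for _ in range(200):
        n_actions = rng.integers(1, 5)
        actions = tuple(f"a{i}" for i in range(n_actions))
        model = TransitionModel.uniform(CUES, actions, OUTCOMES)
        for key in model.counts:
            model.counts[key] = float(rng.uniform(0.01, 10.0))
        values = OutcomeValueTable(
            {o: float(rng.uniform(-1, 0)) for o in OUTCOMES}
        )
        buf = plan_values(model, values, "c0")
        oracle = brute_force_expectations(model, values, "c0")
        for a in actions:
            assert abs(buf.q[a] - oracle[a]) < 1e-12


def test_plan_values_unknown_cue_raises():
    model = model_with_probs({"LP": 0.5})
    with pytest.raises(ValueError):
        plan_values(model, OutcomeValueTable.zeros(OUTCOMES), "nope")


def test_argmax_ties_broken_by_action_order():
    values = OutcomeValueTable.zeros(OUTCOMES)
    model = TransitionModel.uniform(CUES, ("z_first", "a_second"), OUTCOMES)
    buf = plan_values(model, values, "c0")
    assert buf.best_action == "z_first"


def test_choose_plan_uniform_when_values_equal(rng):
    buf = ActionValueBuffer({"a": -0.5, "b": -0.5, "c": -0.5}, "a", -0.5)
    plan = choose_plan(buf, 0.25, rng)
    for p in plan.choice_probs.values():
        assert p == pytest.approx(1 / 3)


def test_choose_plan_closed_form_softmax(rng):
    buf = ActionValueBuffer({"a": 0.0, "b": -1.0}, "a", 0.0)
    plan = choose_plan(buf, 1.0, rng)
    expected = math.exp(0.0) / (math.exp(0.0) + math.exp(-1.0))
    assert plan.choice_probs["a"] == pytest.approx(expected, abs=1e-12)
    assert sum(plan.choice_probs.values()) == pytest.approx(1.0, abs=1e-12)


def test_choose_plan_greedy_limit(rng):
    buf = ActionValueBuffer({"a": 0.0, "b": -1.0, "c": -1.0}, "a", 0.0)
    plan = choose_plan(buf, 1e-4, rng)
    assert plan.choice_probs["a"] == pytest.approx(1.0)
    assert plan.action == "a"


def test_choose_plan_activation_is_buffer_max_not_chosen_value():
    """The plan node inherits the best buffered value even when softmax
    samples a worse action."""
    buf = ActionValueBuffer({"a": 0.0, "b": -0.2}, "a", 0.0)
    rng = np.random.default_rng(5)
    seen_b = False
    for _ in range(200):
        plan = choose_plan(buf, 1.0, rng)
        assert plan.activation == 0.0
        seen_b = seen_b or plan.action == "b"
    assert seen_b


def test_choose_plan_bad_temperature_raises(rng):
    buf = ActionValueBuffer({"a": 0.0}, "a", 0.0)
    for temp in (0.0, -1.0):
        with pytest.raises(ValueError):
            choose_plan(buf, temp, rng)


@given(
    q=st.lists(st.floats(-10, 10), min_size=2, max_size=5),
    temp=st.floats(0.5, 10.0),
)
@settings(deadline=None, derandomize=True)
def test_stable_softmax_equals_naive_formula(q, temp):
    """Within the range where the naive softmax is finite, the
    max-subtracted computation agrees with it."""
    actions = [f"a{i}" for i in range(len(q))]
    qmap = dict(zip(actions, q))
    best = max(qmap, key=lambda a: (qmap[a], -actions.index(a)))
    buf = ActionValueBuffer(qmap, best, max(q))
    plan = choose_plan(buf, temp, np.random.default_rng(0))
    z = sum(math.exp(v / temp) for v in q)
    for a in actions:
        naive = math.exp(qmap[a] / temp) / z
        assert plan.choice_probs[a] == pytest.approx(naive, abs=1e-12, rel=1e-9)


def test_update_transition_count_arithmetic():
    """Pseudocount 1 plus a single observation gives P = 2/3; only the
    experienced triple changes."""
    model = TransitionModel.uniform(("red",), ("LP",), OUTCOMES)
    update_transition(model, "red", "LP", "low_tone")
    assert model.prob("red", "LP", "low_tone") == pytest.approx(2 / 3)
    assert model.counts[("red", "LP", "high_tone")] == 1.0


def test_update_transition_validation():
    model = TransitionModel.uniform(("red",), ("LP",), OUTCOMES)
    with pytest.raises(ValueError):
        update_transition(model, "blue", "LP", "low_tone")
    with pytest.raises(ValueError):
        update_transition(model, "red", "CP", "low_tone")
    with pytest.raises(ValueError):
        update_transition(model, "red", "LP", "mid_tone")
    with pytest.raises(ValueError):
        update_transition(model, "red", "LP", "low_tone", increment=0.0)


def test_transition_probabilities_concentrate():
    """10,000 draws at shock rate 0.8 put the learned conditional within
    0.02 of truth."""
    rng = np.random.default_rng(77)
    model = TransitionModel.uniform(("black",), ("CP",), OUTCOMES)
    for _ in range(10_000):
        tone = "high_tone" if rng.random() < 0.8 else "low_tone"
        update_transition(model, "black", "CP", tone)
    assert abs(model.prob("black", "CP", "high_tone") - 0.8) < 0.02


@given(
    updates=st.lists(
        st.tuples(st.sampled_from(["a0", "a1"]), st.sampled_from(OUTCOMES)),
        max_size=30,
    )
)
@settings(deadline=None, derandomize=True)
def test_probabilities_always_normalised_and_positive(updates):
    model = TransitionModel.uniform(CUES, ("a0", "a1"), OUTCOMES)
    for action, tone in updates:
        update_transition(model, "c0", action, tone)
    for a in ("a0", "a1"):
        probs = model.outcome_probs("c0", a)
        assert abs(sum(probs.values()) - 1.0) < 1e-12
        assert all(p > 0 for p in probs.values())


def test_update_outcome_value_delta_rule():
    values = OutcomeValueTable.zeros(OUTCOMES)
    update_outcome_value(values, "high_tone", -1.0, 0.2)
    assert values.v["high_tone"] == pytest.approx(-0.2)
    assert values.v["low_tone"] == 0.0
    # zero prediction error leaves the value unchanged
    update_outcome_value(values, "low_tone", 0.0, 0.2)
    assert values.v["low_tone"] == 0.0


def test_update_outcome_value_fixed_point():
    """Repeated shock outcomes drive the shock-tone value to the reinforcer."""
    values = OutcomeValueTable.zeros(OUTCOMES)
    for _ in range(200):
        update_outcome_value(values, "high_tone", -1.0, 0.1)
    assert values.v["high_tone"] == pytest.approx(-1.0, abs=1e-6)


@pytest.mark.parametrize("alpha", [0.0, -0.1, 1.5])
def test_update_outcome_value_bad_alpha_raises(alpha):
    values = OutcomeValueTable.zeros(OUTCOMES)
    with pytest.raises(ValueError):
        update_outcome_value(values, "high_tone", -1.0, alpha)
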