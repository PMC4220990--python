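import math

import hypothesis.strategies as st
import numpy as np
import pytest
from hypothesis import given, settings

from cssmkit.domain import (
    ActionSchema,
    Domain,
    DomainError,
    NotApplicableError,
    SlotSpec,
    WAIT_CLASS,
    applicable_actions,
    apply_action,
    detect_livelocks,
    dumps_domain,
    goal_distance_complete,
    goal_distance_restricted,
    loads_domain,
    reachable_states,
    script_distance,
)

from .oracles import bfs_distances


def test_ground_actions_tiny(tiny_domain):
    ids = [a.id for a in tiny_domain.ground]
    assert ids == sorted(ids)
    assert len(ids) == len(set(ids))
    # put grounds over two items; the four 0-ary schemata stay bare; wait appended
    assert "put(cup)" in ids and "put(plate)" in ids
    assert "cook" in ids and "wait" in ids
    assert len(ids) == 7


def test_wait_semantics(tiny_domain):
    s = tiny_domain.initial
    w = tiny_domain.wait_action
    assert w.class_label == WAIT_CLASS
    assert apply_action(tiny_domain, s, w) == s
    assert w in applicable_actions(tiny_domain, s)


def test_apply_and_preconditions(tiny_domain):
    d = tiny_domain
    s = d.initial
    cook = d.actions_by_id["cook"]
    with pytest.raises(NotApplicableError):
        apply_action(d, s, cook)  # stove is off
    s2 = apply_action(d, s, d.actions_by_id["turn_on"])
    assert d.slot_value(s2, "stove") == "on"
    s3 = apply_action(d, s2, cook)
    assert d.slot_value(s3, "food") == "cooked"
    # original state untouched (states are immutable tuples)
    assert d.slot_value(s, "stove") == "off"


def test_int_slot_bounds():
    d = Domain(
        objects={},
        slots=[SlotSpec("n", (0, 1, 2), is_int=True)],
        schemata=[
            ActionSchema.parse("inc", pre=["n <= 1"], eff=["n += 1"], class_label="A"),
            ActionSchema.parse("over", pre=[], eff=["n += 5"], class_label="A"),
        ],
        initial={"n": 0},
        goal={"n": 2},
    )
    s = apply_action(d, d.initial, d.actions_by_id["inc"])
    assert d.slot_value(s, "n") == 1
    with pytest.raises(DomainError):
        apply_action(d, d.initial, d.actions_by_id["over"])


def test_reachable_tiny(tiny_domain, tiny_graph):
    assert len(tiny_graph.states) == 18
    assert not tiny_graph.truncated
    assert tiny_graph.states[0] == tiny_domain.initial
    assert len(tiny_graph.goal_states()) == 1
    assert detect_livelocks(tiny_graph) == set()


def test_goal_distance_matches_bfs(tiny_domain, tiny_graph):
    dist = goal_distance_complete(tiny_graph)
    goal_idx = [tiny_graph.index[s] for s in tiny_graph.goal_states()]
    wait_id = tiny_domain.wait_action.id
    edges = [(i, j) for i, aid, j in tiny_graph.edges if aid != wait_id]
    ref = bfs_distances(edges, goal_idx, len(tiny_graph.states))
    for s, i in tiny_graph.index.items():
        assert dist[s] == ref[i]


def test_restricted_distance_dominates(tiny_domain, tiny_graph):
    full = goal_distance_complete(tiny_graph)
    allowed = set(list(tiny_graph.states)[:10]) | set(tiny_graph.goal_states())
    restr = goal_distance_restricted(tiny_graph, allowed=allowed)
    for s in allowed:
        assert restr[s] >= full[s]


def test_script_distance_monotone(tiny_domain):
    d = tiny_domain
    s = d.initial
    seq = ["put(cup)", "put(plate)", "turn_on", "cook", "eat", "turn_off"]
    values = [script_distance(d, s)]
    for aid in seq:
        s = apply_action(d, s, d.actions_by_id[aid])
        values.append(script_distance(d, s))
    assert values[0] > values[-1]
    assert values[-1] == 0
    assert sorted(values, reverse=True) == values  # never increases along the plan


def test_yaml_round_trip(tiny_domain, tiny_graph):
    d2 = loads_domain(dumps_domain(tiny_domain))
    assert [a.id for a in d2.ground] == [a.id for a in tiny_domain.ground]
    assert d2.initial == tiny_domain.initial
    g2 = reachable_states(d2, cap=1000)
    assert len(g2.states) == len(tiny_graph.states)
    assert script_distance(d2, d2.initial) == script_distance(tiny_domain, tiny_domain.initial)


def test_duplicate_action_ids_rejected():
    with pytest.raises(DomainError):
        Domain(
            objects={},
            slots=[SlotSpec("x", ("a", "b"))],
            schemata=[
                ActionSchema.parse("go", pre=[], eff=["x := b"], class_label="A"),
                ActionSchema.parse("go", pre=[], eff=["x := a"], class_label="B"),
            ],
            initial={"x": "a"},
            goal={"x": "b"},
        ).ground


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 9))
def test_random_walk_stays_in_slot_domains(tiny_domain, seed):
    d = tiny_domain
    rng = np.random.default_rng(seed)
    s = d.initial
    for _ in range(15):
        acts = applicable_actions(d, s)
        a = acts[rng.integers(len(acts))]
        s = apply_action(d, s, a)
        for slot, v in zip(d.slots, s):
            assert v in slot.values


def test_branching_summary(tiny_graph):
    b = tiny_graph.branching_summary()
    assert b["median"] >= 1
    assert b["q1"] <= b["median"] <= b["q3"]
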