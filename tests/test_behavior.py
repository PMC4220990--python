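import math

import numpy as np
import pytest

from cssmkit.behavior import SelectionModel, selection_distribution, simulate_trace
from cssmkit.domain import applicable_actions, apply_action, goal_distance_complete

from .oracles import selection_row


def test_uniform_distribution(tiny_domain):
    dist = selection_distribution(tiny_domain, SelectionModel.uniform(), tiny_domain.initial)
    acts = applicable_actions(tiny_domain, tiny_domain.initial)
    assert set(dist) == set(acts)
    assert all(p == pytest.approx(1.0 / len(acts)) for p in dist.values())


def test_boltzmann_zero_weight_is_uniform(tiny_domain, tiny_graph):
    d = goal_distance_complete(tiny_graph)
    u = selection_distribution(tiny_domain, SelectionModel.uniform(), tiny_domain.initial)
    b = selection_distribution(tiny_domain, SelectionModel.heuristic(d, 0.0),
                               tiny_domain.initial)
    for a in u:
        assert b[a] == pytest.approx(u[a])


@pytest.mark.parametrize("weight", [0.5, 1.0, 2.0, 8.0])
def test_boltzmann_matches_direct_formula(tiny_domain, tiny_graph, weight):
    d = goal_distance_complete(tiny_graph)
    model = SelectionModel.heuristic(d, weight)
    for s in list(tiny_graph.states)[:8]:
        got = selection_distribution(tiny_domain, model, s)
        ref = selection_row(tiny_domain, model, s)
        assert set(got) == set(ref)
        for a in got:
            assert got[a] == pytest.approx(ref[a], abs=1e-12)
        assert sum(got.values()) == pytest.approx(1.0)


def test_high_weight_concentrates_on_argmin(tiny_domain, tiny_graph):
    d = goal_distance_complete(tiny_graph)
    s = tiny_domain.initial
    dist = selection_distribution(tiny_domain, SelectionModel.heuristic(d, 50.0), s)
    best = min(dist, key=lambda a: d[apply_action(tiny_domain, s, a)])
    assert dist[best] > 0.99 or sum(
        p for a, p in dist.items()
        if d[apply_action(tiny_domain, s, a)] == d[apply_action(tiny_domain, s, best)]
    ) > 0.99


def test_epsilon_greedy_mixture(tiny_domain, tiny_graph):
    d = goal_distance_complete(tiny_graph)
    model = SelectionModel.epsilon_greedy(d, epsilon=0.2)
    s = tiny_domain.initial
    got = selection_distribution(tiny_domain, model, s)
    ref = selection_row(tiny_domain, model, s)
    for a in got:
        assert got[a] == pytest.approx(ref[a], abs=1e-12)
    assert sum(got.values()) == pytest.approx(1.0)


def test_tabular_errors(tiny_domain):
    model = SelectionModel.tabular({})
    with pytest.raises(KeyError):
        selection_distribution(tiny_domain, model, tiny_domain.initial)
    acts = applicable_actions(tiny_domain, tiny_domain.initial)
    row = {a.id: 0.0 for a in acts}
    with pytest.raises(ValueError):
        selection_distribution(
            tiny_domain, SelectionModel.tabular({tiny_domain.initial: row}),
            tiny_domain.initial)


def test_invalid_models():
    with pytest.raises(ValueError):
        SelectionModel(kind="nope")
    with pytest.raises(ValueError):
        SelectionModel(kind="heuristic", feature={}, weight=-1.0)
    with pytest.raises(ValueError):
        SelectionModel(kind="heuristic")


def test_simulate_trace_consistency(tiny_domain, tiny_graph, tiny_bank):
    d = goal_distance_complete(tiny_graph)
    policy = SelectionModel.epsilon_greedy(d, epsilon=0.1)
    tr = simulate_trace(tiny_domain, policy, tiny_bank, frame_rate=2.0,
                        horizon=500, seed=11)
    assert tr.goal_reached and not tr.horizon_hit
    # segment states follow from applying the action sequence
    s = tiny_domain.initial
    for seg in tr.segments:
        if seg.action_id != tiny_domain.wait_action.id:
            a = tiny_domain.actions_by_id[seg.action_id]
            s = apply_action(tiny_domain, s, a)
        assert seg.state == s
        assert seg.n_frames >= 1
    assert tr.n_frames == sum(seg.n_frames for seg in tr.segments)
    assert len(tr.frame_labels) == tr.n_frames
    assert np.all(np.diff(tr.timestamps) > 0)
    assert tiny_domain.goal_satisfied(tr.segments[-1].state)


def test_simulate_trace_deterministic(tiny_domain, tiny_graph, tiny_bank):
    d = goal_distance_complete(tiny_graph)
    policy = SelectionModel.epsilon_greedy(d, epsilon=0.1)
    t1 = simulate_trace(tiny_domain, policy, tiny_bank, seed=5)
    t2 = simulate_trace(tiny_domain, policy, tiny_bank, seed=5)
    assert [s.action_id for s in t1.segments] == [s.action_id for s in t2.segments]
    assert [s.n_frames for s in t1.segments] == [s.n_frames for s in t2.segments]


def test_durations_by_class(tiny_domain, tiny_graph, tiny_bank):
    d = goal_distance_complete(tiny_graph)
    tr = simulate_trace(tiny_domain, SelectionModel.epsilon_greedy(d), tiny_bank, seed=2)
    by_class = tr.durations_by_class()
    assert all(v > 0 for vs in by_class.values() for v in vs)
    assert set(by_class) <= set(tiny_domain.classes)


def test_trace_frame_table(tiny_domain, tiny_graph, tiny_bank, tmp_path):
    d = goal_distance_complete(tiny_graph)
    tr = simulate_trace(tiny_domain, SelectionModel.epsilon_greedy(d), tiny_bank, seed=2)
    df = tr.to_frame()
    assert len(df) == tr.n_frames
    assert {"timestamp", "action", "class"} <= set(df.columns)
    out = tmp_path / "trace.tsv"
    tr.save(out)
    assert out.read_text().count("\n") == tr.n_frames + 1
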