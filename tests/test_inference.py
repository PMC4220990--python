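import math

import numpy as np
import pytest
from scipy.special import logsumexp

from cssmkit.behavior import SelectionModel, simulate_trace
from cssmkit.domain import goal_distance_complete
from cssmkit.durations import DurationModel
from cssmkit.inference import (
    Belief,
    INIT_ACTION_ID,
    InferenceState,
    ObservationImpossibleError,
    mf_filter,
    mf_predict,
    mf_smooth,
    mf_update,
    mf_viterbi,
    pf_filter,
    point_estimate,
    predicate_track,
    representation_accounting,
)
from cssmkit.observations import LocationSensorModel, make_class_spec

from . import oracles

UNPRUNED = 10 ** 9


@pytest.fixture(scope="module")
def tiny_setup(tiny_domain, tiny_graph, tiny_bank):
    d = goal_distance_complete(tiny_graph)
    selection = SelectionModel.heuristic(d, 1.5)
    obs_model = LocationSensorModel(
        domain=tiny_domain,
        slot_names=("loc(cup)", "loc(plate)", "stove", "food"),
        epsilon=0.15,
    )
    tr = simulate_trace(tiny_domain, SelectionModel.epsilon_greedy(d, 0.1),
                        tiny_bank, frame_rate=2.0, seed=17)
    rng = np.random.default_rng(23)
    obs = [obs_model.observe(s, rng) for s in tr.frame_states[:12]]
    ts = tr.timestamps[:12]
    return tiny_domain, tiny_bank, selection, obs_model, obs, ts, tr


def _marginal_errors(result, exact_steps, aclass):
    errs = []
    for step, exact in zip(result.steps, exact_steps):
        got = {c: 0.0 for c in result.classes}
        for x, w in zip(step.entries, np.exp(step.log_weights)):
            got[aclass[x.action_id]] += w
        ref = oracles.class_marginal(exact, aclass, result.classes)
        errs.append(max(abs(got[c] - ref[c]) for c in result.classes))
    return errs


def test_unpruned_filter_matches_exact(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=UNPRUNED,
                       timestamps=ts)
    exact_steps, exact_log, aclass = oracles.exact_filter(
        domain, bank, selection, obs_model, obs, ts)
    assert max(_marginal_errors(result, exact_steps, aclass)) < 1e-9
    # state-level posteriors agree too, and evidence increments match
    for step, exact in zip(result.steps, exact_steps):
        for x, w in zip(step.entries, np.exp(step.log_weights)):
            assert w == pytest.approx(exact[(x.state, x.action_id, x.st)], abs=1e-9)
    assert np.allclose(result.log_evidence_increments, exact_log, atol=1e-9)


def test_predict_update_composition(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=UNPRUNED,
                       timestamps=ts)
    dt0 = ts[1] - ts[0]
    init = InferenceState(domain.initial, INIT_ACTION_ID, float(ts[0] - dt0))
    belief = Belief([init], np.zeros(1), time=float(ts[0] - dt0))
    for t, o, step in zip(ts, obs, result.steps):
        prior = mf_predict(belief, float(t), domain, bank, selection)
        belief = mf_update(prior, o, obs_model, K=UNPRUNED, domain=domain)
        got = dict(zip(belief.entries, np.exp(belief.log_weights)))
        ref = dict(zip(step.entries, np.exp(step.log_weights)))
        assert set(got) == set(ref)
        for k in got:
            assert got[k] == pytest.approx(ref[k], abs=1e-12)


def test_filter_weights_are_distributions(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=5, timestamps=ts)
    for step in result.steps:
        assert len(step.entries) <= 5
        assert len(set(step.entries)) == len(step.entries)
        assert logsumexp(step.log_weights) == pytest.approx(0.0, abs=1e-12)


def test_update_prunes_to_top_k(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    dt0 = ts[1] - ts[0]
    init = InferenceState(domain.initial, INIT_ACTION_ID, float(ts[0] - dt0))
    belief = Belief([init], np.zeros(1), time=float(ts[0] - dt0))
    for t, o in zip(ts[:4], obs[:4]):
        belief = mf_update(mf_predict(belief, float(t), domain, bank, selection),
                           o, obs_model, K=UNPRUNED, domain=domain)
    prior = mf_predict(belief, float(ts[4]), domain, bank, selection)
    full = mf_update(prior, obs[4], obs_model, K=UNPRUNED, domain=domain)
    pruned = mf_update(prior, obs[4], obs_model, K=3, domain=domain)
    assert len(pruned.entries) == 3
    # the kept set is exactly the 3 highest-posterior entries, renormalised
    order = np.argsort(-full.log_weights)[:3]
    assert set(pruned.entries) == {full.entries[i] for i in order}
    top = full.log_weights[order]
    expect = top - logsumexp(top)
    got = {e: w for e, w in zip(pruned.entries, pruned.log_weights)}
    for i, e in zip(order, [full.entries[i] for i in order]):
        assert got[e] == pytest.approx(expect[list(order).index(i)], abs=1e-12)


def test_smoothing_matches_exact_when_unpruned(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=UNPRUNED,
                       timestamps=ts)
    sm = mf_smooth(result)
    exact = oracles.exact_smooth(domain, bank, selection, obs_model, obs, ts)
    for k, (step, lw) in enumerate(zip(result.steps, sm)):
        for x, w in zip(step.entries, np.exp(lw)):
            assert w == pytest.approx(exact[k][(x.state, x.action_id, x.st)], abs=1e-9)
    # last smoothed step equals the filtered one
    assert np.allclose(sm[-1], result.steps[-1].log_weights)


def test_viterbi_matches_exhaustive(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=UNPRUNED,
                       timestamps=ts)
    path, classes = mf_viterbi(result)
    ref_path, ref_score = oracles.exact_viterbi(
        domain, bank, selection, obs_model, obs, ts)
    got = [(x.state, x.action_id, x.st) for x in path]
    assert got == ref_path
    assert len(classes) == len(obs)


def test_class_keyed_filter_runs(tiny_domain, tiny_graph, tiny_bank):
    d = goal_distance_complete(tiny_graph)
    selection = SelectionModel.heuristic(d, 1.0)
    spec = make_class_spec(tiny_domain.classes, dim=4, separation=3.0)
    tr = simulate_trace(tiny_domain, SelectionModel.epsilon_greedy(d), tiny_bank, seed=3)
    from cssmkit.observations import generate_observations

    x = generate_observations(tr.frame_labels, spec, seed=5)
    result = mf_filter(tiny_domain, tiny_bank, selection, spec.to_gaussian_model(),
                       x, K=50, timestamps=tr.timestamps)
    est = result.point_estimates()
    assert len(est) == len(x)
    acc = np.mean([a == b for a, b in zip(est, tr.frame_labels)])
    assert acc > 0.6  # well-separated classes: far above the 1/6 chance level


def test_observation_impossible(tiny_domain, tiny_bank):
    exact_obs = LocationSensorModel(domain=tiny_domain, slot_names=("food",), epsilon=0.0)
    selection = SelectionModel.uniform()
    # food can never be "eaten" at the first frame (two actions needed first)
    with pytest.raises(ObservationImpossibleError):
        mf_filter(tiny_domain, tiny_bank, selection, exact_obs, [("eaten",)],
                  K=UNPRUNED, frame_rate=2.0)


def test_pf_matches_exact_loosely(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    exact_steps, _, aclass = oracles.exact_filter(
        domain, bank, selection, obs_model, obs, ts)
    result = pf_filter(domain, bank, selection, obs_model, obs, N=4000,
                       seed=0, timestamps=ts)
    errs = _marginal_errors(result, exact_steps, aclass)
    assert max(errs) < 0.1
    for step in result.steps:
        assert 1.0 <= step.ess <= result.units + 1e-9
        assert logsumexp(step.log_weights) == pytest.approx(0.0, abs=1e-9)


def test_pf_deterministic_given_seed(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    r1 = pf_filter(domain, bank, selection, obs_model, obs, N=300, seed=9, timestamps=ts)
    r2 = pf_filter(domain, bank, selection, obs_model, obs, N=300, seed=9, timestamps=ts)
    assert np.allclose(r1.class_marginal_matrix(), r2.class_marginal_matrix())


def test_predicate_track_bounds_and_point_estimate(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=20, timestamps=ts)
    stove_on = domain.predicate({"stove": "on"})
    track = predicate_track(result, stove_on)
    assert np.all((track >= -1e-12) & (track <= 1 + 1e-12))
    sm_track = predicate_track(result, stove_on, mode="smoothed")
    assert sm_track.shape == track.shape
    assert point_estimate({"A": 0.2, "B": 0.5, "C": 0.3}) == "B"
    assert point_estimate({"A": 0.5, "B": 0.5}) == "A"  # deterministic tie-break


def test_representation_accounting(tiny_setup):
    domain, bank, selection, obs_model, obs, ts, _ = tiny_setup
    result = mf_filter(domain, bank, selection, obs_model, obs, K=10, timestamps=ts)
    acct = representation_accounting(result)
    assert (acct["n_x"] <= 10).all()
    assert (acct["n_states"] <= acct["n_x"]).all()
    assert (acct["xps"] >= 1.0).all()
    assert np.allclose(acct["xpu"], acct["n_x"] / 10)


def test_one_frame_duration_forces_termination(tiny_domain):
    bank = {c: DurationModel("empirical", ((0.5,), (1.0,))) for c in tiny_domain.classes}
    obs_model = LocationSensorModel(domain=tiny_domain, slot_names=("stove",), epsilon=0.3)
    result = mf_filter(tiny_domain, bank, SelectionModel.uniform(), obs_model,
                       [("off",)] * 5, K=UNPRUNED, frame_rate=2.0)
    for k, step in enumerate(result.steps):
        # with hazard 1 every entry restarts at the current timestamp
        assert all(x.st == pytest.approx(result.timestamps[k]) for x in step.entries)
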