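"""Built-in kitchen-style domains, synthetic data, and the experiment harness.

The scenario is a scaled-down meal-time routine: prepare and cook food, set
the table, eat and drink, then clear and wash the dishes.  Two scales ship:

- ``tiny``: a handful of slots, at most a few dozen reachable states — small
  enough for brute-force exact-inference oracles;
- ``small``: seven table items whose set-table and clean-up subtasks can be
  permuted freely, giving >= 1e4 reachable states and the high-dispersion
  structure (many trajectories meeting in the same state) under which set-
  based filtering pays off.

The harness simulates ground-truth traces with an epsilon-greedy behavior
policy, synthesises class-conditional Gaussian observations, fits the
baselines and observation/duration models on the pooled replicates, runs
each configured method, and scores everything against the truth labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import baselines, evaluation, inference, observations
from .behavior import SelectionModel, Trace, simulate_trace
from .domain import (
    ActionSchema,
    Domain,
    SlotSpec,
    StateGraph,
    goal_distance_complete,
    goal_distance_restricted,
    reachable_states,
)
from .durations import DegenerateSamplesError, DurationModel, fit as fit_duration

__all__ = [
    "make_kitchen_domain",
    "default_duration_bank",
    "fit_duration_bank",
    "ExperimentConfig",
    "MethodSpec",
    "run_experiment",
]

_TINY_ITEMS = ("cup", "plate")
_SMALL_ITEMS = ("bowl", "cup", "fork", "knife", "plate", "pot", "spoon")
_EAT_ITEMS = ("fork", "plate", "spoon")  # must be on the table before eating


def make_kitchen_domain(scale: str = "tiny") -> Domain:
    """A self-contained meal-routine domain at the requested scale."""
    if scale == "tiny":
        slots = [
            SlotSpec("loc(cup)", ("shelf", "table")),
            SlotSpec("loc(plate)", ("shelf", "table")),
            SlotSpec("stove", ("off", "on")),
            SlotSpec("food", ("raw", "cooked", "eaten")),
        ]
        schemata = [
            ActionSchema.parse("put", params=[("x", "item")], class_label="PUT",
                               pre=["loc(?x) == shelf"], eff=["loc(?x) := table"]),
            ActionSchema.parse("turn_on", class_label="TURN_ON",
                               pre=["stove == off"], eff=["stove := on"]),
            ActionSchema.parse("turn_off", class_label="TURN_OFF",
                               pre=["stove == on"], eff=["stove := off"]),
            ActionSchema.parse("cook", class_label="COOK",
                               pre=["stove == on", "food == raw"], eff=["food := cooked"]),
            ActionSchema.parse("eat", class_label="EAT",
                               pre=["food == cooked", "loc(cup) == table",
                                    "loc(plate) == table"],
                               eff=["food := eaten"]),
        ]
        initial = {"loc(cup)": "shelf", "loc(plate)": "shelf", "stove": "off", "food": "raw"}
        goal = {"food": "eaten", "stove": "off"}
        script = [
            ({"food": "eaten", "stove": "off"}, 0),
            ({"food": "eaten"}, 1),
            ({"food": "cooked"}, 2),
            ({"stove": "on"}, 3),
            ({}, 4),
        ]
        return Domain(objects={"item": _TINY_ITEMS}, slots=slots, schemata=schemata,
                      initial=initial, goal=goal, script=script, name="kitchen-tiny")
    if scale == "small":
        slots = [SlotSpec(f"loc({it})", ("cupboard", "table", "sink")) for it in _SMALL_ITEMS]
        slots += [
            SlotSpec("stove", ("off", "on")),
            SlotSpec("food", ("raw", "prepared", "cooked", "eaten")),
            SlotSpec("drink", ("full", "empty")),
        ]
        schemata = [
            ActionSchema.parse("put", params=[("x", "item")], class_label="PUT",
                               pre=["loc(?x) == cupboard"], eff=["loc(?x) := table"]),
            ActionSchema.parse("stow", params=[("x", "item")], class_label="TAKE",
                               pre=["loc(?x) == table"], eff=["loc(?x) := cupboard"]),
            ActionSchema.parse("clear", params=[("x", "item")], class_label="TAKE",
                               pre=["loc(?x) == table", "food == eaten"],
                               eff=["loc(?x) := sink"]),
            ActionSchema.parse("wash", params=[("x", "item")], class_label="WASH",
                               pre=["loc(?x) == sink"], eff=["loc(?x) := cupboard"]),
            ActionSchema.parse("prepare", class_label="PREPARE",
                               pre=["food == raw"], eff=["food := prepared"]),
            ActionSchema.parse("turn_on", class_label="TURN_ON",
                               pre=["stove == off"], eff=["stove := on"]),
            ActionSchema.parse("turn_off", class_label="TURN_OFF",
                               pre=["stove == on"], eff=["stove := off"]),
            ActionSchema.parse("cook", class_label="COOK",
                               pre=["stove == on", "food == prepared"],
                               eff=["food := cooked"]),
            ActionSchema.parse("eat", class_label="EAT",
                               pre=["food == cooked"]
                               + [f"loc({it}) == table" for it in _EAT_ITEMS],
                               eff=["food := eaten"]),
            ActionSchema.parse("drink", class_label="DRINK",
                               pre=["drink == full", "loc(cup) == table"],
                               eff=["drink := empty"]),
        ]
        initial = {f"loc({it})": "cupboard" for it in _SMALL_ITEMS}
        initial.update({"stove": "off", "food": "raw", "drink": "full"})
        goal = {f"loc({it})": "cupboard" for it in _SMALL_ITEMS}
        goal.update({"stove": "off", "food": "eaten", "drink": "empty"})
        script = [
            (dict(goal), 0),
            ({"food": "eaten", "drink": "empty"}, 1),
            ({"food": "eaten"}, 2),
            ({"food": "cooked"}, 3),
            ({"food": "prepared", "stove": "on"}, 4),
            ({"food": "prepared"}, 5),
            ({}, 6),
        ]
        return Domain(objects={"item": _SMALL_ITEMS}, slots=slots, schemata=schemata,
                      initial=initial, goal=goal, script=script, name="kitchen-small")
    raise ValueError(f"unknown scale {scale!r} (expected 'tiny' or 'small')")


def default_duration_bank(domain: Domain, frame_rate: float = 2.0) -> dict:
    """Per-class generative duration models (seconds) for the kitchen domains.

    Lognormal for manipulative classes, gamma for washing, Weibull for
    cooking, exponential for waiting — medians of one to a few seconds so a
    full routine spans on the order of a hundred frames at 2 Hz.
    """
    bank = {
        "TAKE": DurationModel("lognormal", (math.log(2.0), 0.35)),
        "PUT": DurationModel("lognormal", (math.log(2.0), 0.35)),
        "WASH": DurationModel("gamma", (3.0, 1.0)),
        "COOK": DurationModel("weibull", (2.0, 5.0)),
        "EAT": DurationModel("lognormal", (math.log(6.0), 0.4)),
        "DRINK": DurationModel("lognormal", (math.log(3.0), 0.4)),
        "TURN_ON": DurationModel("lognormal", (math.log(1.0), 0.3)),
        "TURN_OFF": DurationModel("lognormal", (math.log(1.0), 0.3)),
        "PREPARE": DurationModel("gamma", (4.0, 1.0)),
        "WAIT": DurationModel("exponential", (0.4,)),
    }
    return {c: bank[c] for c in domain.classes}


def fit_duration_bank(traces: Sequence[Trace], family: str = "lognormal",
                      classes: Sequence | None = None) -> dict:
    """Fit per-class duration models from pooled trace annotations.

    Classes whose pooled durations cannot support the family (fewer than two
    observations, or no spread) fall back to the empirical family.
    """
    pooled: dict = {}
    for tr in traces:
        for c, ds in tr.durations_by_class().items():
            pooled.setdefault(c, []).extend(ds)
    bank = {}
    for c in classes or pooled.keys():
        ds = pooled.get(c, [])
        if len(ds) < 2:
            ds = ds or [1.0]
            values = sorted(set(ds))
            probs = [ds.count(v) / len(ds) for v in values]
            bank[c] = DurationModel("empirical", (tuple(values), tuple(probs)))
            continue
        try:
            bank[c] = fit_duration(family, ds)
        except DegenerateSamplesError:
            bank[c] = fit_duration("empirical", ds)
    return bank


@dataclass
class MethodSpec:
    """One inference method to run in the harness.

    kinds: ``qda``, ``hmm_f``, ``hmm_s``, ``hmm_v``, ``mf_f``, ``mf_s``,
    ``mf_v``, ``pf_f``.  For CSSM methods, ``weight`` is the selection
    weight lambda and ``distance`` one of ``complete``/``restricted``/
    ``script``; ``units`` is K (marginal) or N (particles).
    """

    name: str
    kind: str
    units: int = 200
    weight: float = 1.0
    distance: str = "restricted"


@dataclass
class ExperimentConfig:
    """Study conditions for a harness run (defaults = standard conditions)."""

    scale: str = "small"
    replicates: int = 7
    frame_rate: float = 2.0
    horizon: int = 400
    behavior_epsilon: float = 0.15
    obs_dim: int = 6
    obs_separation: float = 2.5  # frame-wise Bayes error ~0.27 for 10 classes in 6-d
    obs_sigma: float = 1.0
    obs_drift: float = 0.0
    scramble: bool = True
    duration_family: str = "lognormal"
    methods: tuple = (
        MethodSpec("qda", "qda"),
        MethodSpec("hmm_f", "hmm_f"),
        MethodSpec("hmm_s", "hmm_s"),
        MethodSpec("mf_f", "mf_f"),
        MethodSpec("pf_f", "pf_f"),
    )


def _distance_feature(name: str, domain: Domain, graph: StateGraph, visited: set):
    if name == "complete":
        return goal_distance_complete(graph)
    if name == "restricted":
        allowed = set(visited) | {domain.initial}
        return goal_distance_restricted(graph, allowed=allowed)
    if name == "script":
        from .domain import script_distance

        return lambda state: script_distance(domain, state)
    raise ValueError(f"unknown distance feature {name!r}")


def run_experiment(config: ExperimentConfig, seed: int = 0) -> pd.DataFrame:
    """Run every configured method on every replicate and score it.

    Per replicate: simulate a ground-truth trace, generate observations,
    then (pooled over all replicates, mirroring a deliberately overfit
    baseline) fit the QDA observation model, the HMM transition counts, and
    the per-class duration models, and run each method.  Errors in one
    method/replicate are recorded as rows with an ``error`` note; the run
    continues.  Deterministic given ``seed``.
    """
    if config.replicates < 1:
        raise ValueError("replicate count must be >= 1")
    sim_root, obs_root, inf_root = np.random.SeedSequence(seed).spawn(3)
    sim_seeds = sim_root.spawn(config.replicates)
    obs_seeds = obs_root.spawn(config.replicates)
    inf_seeds = inf_root.spawn(config.replicates)
    domain = make_kitchen_domain(config.scale)
    gen_bank = default_duration_bank(domain, config.frame_rate)
    graph = reachable_states(domain, cap=200_000)
    d_complete = goal_distance_complete(graph)
    policy = SelectionModel.epsilon_greedy(d_complete, epsilon=config.behavior_epsilon)

    traces = [
        simulate_trace(domain, policy, gen_bank, frame_rate=config.frame_rate,
                       horizon=config.horizon, seed=np.random.default_rng(s))
        for s in sim_seeds
    ]
    spec = observations.make_class_spec(
        domain.classes, dim=config.obs_dim, separation=config.obs_separation,
        sigma=config.obs_sigma, drift=config.obs_drift,
    )
    frames = []
    for tr, s in zip(traces, obs_seeds):
        rng = np.random.default_rng(s)
        x = observations.generate_observations(tr.frame_labels, spec, rng)
        if config.scramble:
            x = observations.scramble(x, tr.frame_labels, rng)
        frames.append(x)

    # pooled fitting (the harness never leaks truth *states* into inference;
    # observation/duration/transition models come from pooled annotations)
    all_x = np.vstack(frames)
    all_labels = np.concatenate([tr.frame_labels for tr in traces])
    qda_model = observations.fit_gaussian_models(all_x, all_labels,
                                                 class_alphabet=domain.classes)
    hmm_model = baselines.fit_hmm([tr.frame_labels for tr in traces],
                                  class_alphabet=domain.classes, obs_model=qda_model)
    inf_bank = fit_duration_bank(traces, family=config.duration_family,
                                 classes=domain.classes)
    visited = {s for tr in traces for s in tr.frame_states}
    feature_cache = {
        name: _distance_feature(name, domain, graph, visited)
        for name in {m.distance for m in config.methods
                     if m.kind in ("mf_f", "mf_s", "mf_v", "pf_f")}
    }

    rows = []
    for r, (tr, x, inf_seed) in enumerate(zip(traces, frames, inf_seeds)):
        truth = list(tr.frame_labels)
        ts = tr.timestamps
        for m in config.methods:
            try:
                est = _run_method(m, domain, inf_bank, qda_model, hmm_model,
                                  feature_cache, x, ts, config, inf_seed)
                estimate, extras = est
                rep = evaluation.score_labels(truth, estimate, classes=domain.classes)
                row = {"replicate": r, "method": m.name, **rep.to_dict(), **extras,
                       "error": ""}
            except Exception as exc:  # noqa: BLE001 - harness keeps going
                row = {"replicate": r, "method": m.name, "error": f"{type(exc).__name__}: {exc}"}
            rows.append(row)
    return pd.DataFrame(rows)


def _run_method(m: MethodSpec, domain, inf_bank, qda_model, hmm_model, feature_cache,
                x, ts, config, inf_seed):
    extras = {}
    if m.kind == "qda":
        _, est = baselines.qda_predict(qda_model, x)
        return est, extras
    if m.kind in ("hmm_f", "hmm_s", "hmm_v"):
        if m.kind == "hmm_f":
            la, _ = baselines.hmm_forward(hmm_model, x)
            est = [hmm_model.classes[i] for i in np.argmax(la, axis=1)]
        elif m.kind == "hmm_s":
            lg = baselines.hmm_smooth(hmm_model, x)
            est = [hmm_model.classes[i] for i in np.argmax(lg, axis=1)]
        else:
            est = baselines.hmm_viterbi(hmm_model, x)
        return est, extras
    feature = feature_cache[m.distance]
    selection = SelectionModel.heuristic(feature, m.weight, feature_name=m.distance,
                                         h_cap=None if not callable(feature) else 100.0)
    if m.kind in ("mf_f", "mf_s", "mf_v"):
        res = inference.mf_filter(domain, inf_bank, selection, qda_model, x,
                                  K=m.units, timestamps=ts,
                                  keep_links=m.kind in ("mf_s", "mf_v"))
        if m.kind == "mf_f":
            est = res.point_estimates()
        elif m.kind == "mf_s":
            est = res.point_estimates(inference.mf_smooth(res))
        else:
            _, est = inference.mf_viterbi(res)
    elif m.kind == "pf_f":
        res = inference.pf_filter(domain, inf_bank, selection, qda_model, x,
                                  N=m.units, seed=np.random.default_rng(inf_seed),
                                  timestamps=ts)
        est = res.point_estimates()
    else:
        raise ValueError(f"unknown method kind {m.kind!r}")
    acct = inference.representation_accounting(res)
    extras["median_xpu"] = float(acct["xpu"].median())
    extras["median_spu"] = float(acct["spu"].median())
    extras["log_evidence"] = res.log_evidence
    return est, extras
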