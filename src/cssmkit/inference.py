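"""Sequential inference for durative-action state space models.

The hidden state at observation time t is the tuple x = (s, a, st): the LTS
state s (already containing the running action's effects), the ground
action a currently executing, and its start time st.  Between observations
the running action either continues (with probability 1 - q, where q is the
duration hazard of its class) or terminates, in which case a successor
action a' is drawn from the action-selection distribution and applied
instantly; start times are restricted to the observed timestamp grid (a
point-distribution approximation that maximises state merging).

Two approximate filters share this transition kernel:

- the *marginal filter* (MF) keeps a finite weighted **set** of distinct
  inference states: duplicate successors are merged by weight summation,
  and after each Bayes update only the K most probable entries are kept
  (renormalised).  Lattice links between retained entries support an
  approximate smoothing recursion and an adapted Viterbi MAP decoder.
- the bootstrap *particle filter* (PF) keeps N weighted samples
  (duplicates allowed), with systematic resampling when the effective
  sample size 1/sum(w^2) drops below a threshold.

All weight arithmetic is in log space (logsumexp merging), so the MF
reproduces a textbook HMM forward pass exactly in the degenerate
configuration of one-frame durations, a tabular selection model, and
class-keyed observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .behavior import SelectionModel, selection_distribution
from .domain import Domain, WAIT_CLASS, apply_action
from .durations import hazard as duration_hazard

__all__ = [
    "InferenceState",
    "Belief",
    "StepRecord",
    "FilterResult",
    "ObservationImpossibleError",
    "mf_predict",
    "mf_update",
    "mf_filter",
    "mf_smooth",
    "mf_viterbi",
    "pf_filter",
    "class_marginals",
    "point_estimate",
    "predicate_track",
    "representation_accounting",
    "INIT_ACTION_ID",
]

INIT_ACTION_ID = "<init>"
_NEG_INF = -math.inf


class InferenceState(NamedTuple):
    """Hidden tuple (LTS state, running ground action, start timestamp)."""

    state: tuple
    action_id: str
    st: float


def _canonical_key(x: InferenceState):
    return (tuple(str(v) for v in x.state), x.action_id, x.st)


class ObservationImpossibleError(RuntimeError):
    """Every retained hypothesis assigns zero likelihood to an observation."""


@dataclass
class Belief:
    """A finite weighted set of distinct inference states (log weights)."""

    entries: list
    log_weights: np.ndarray
    time: float
    capacity: int | None = None

    def __post_init__(self):
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        if len(self.entries) != len(self.log_weights):
            raise ValueError("entries and weights disagree in length")
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate inference states in belief")

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)

    def as_dict(self) -> dict:
        return dict(zip(self.entries, self.weights))

    def normalized(self) -> "Belief":
        z = logsumexp(self.log_weights)
        return Belief(self.entries, self.log_weights - z, self.time, self.capacity)


@dataclass
class StepRecord:
    """Per-observation filtering state: retained entries and lattice links."""

    entries: list  # InferenceState, in retained (pruned) order
    log_weights: np.ndarray  # normalised filtered log weights
    log_lik: np.ndarray  # per-entry observation log-likelihood
    links: list  # (prev_idx, cur_idx, log_transition)
    ess: float | None = None


@dataclass
class FilterResult:
    """Output of a filter run: per-step records plus bookkeeping."""

    mode: str  # "marginal" | "particle"
    classes: tuple
    timestamps: np.ndarray
    steps: list
    log_evidence_increments: np.ndarray
    units: int
    init_entry: InferenceState
    action_classes: Mapping  # action_id -> class label

    @property
    def log_evidence(self) -> float:
        return float(np.sum(self.log_evidence_increments))

    def class_marginal_matrix(self, weights_override=None) -> np.ndarray:
        """(T, C) class marginals from filtered (or supplied) log weights."""
        cindex = {c: i for i, c in enumerate(self.classes)}
        out = np.zeros((len(self.steps), len(self.classes)))
        for k, step in enumerate(self.steps):
            lw = step.log_weights if weights_override is None else weights_override[k]
            w = np.exp(lw)
            for x, wi in zip(step.entries, w):
                out[k, cindex[self.action_classes[x.action_id]]] += wi
        return out

    def point_estimates(self, weights_override=None) -> list:
        m = self.class_marginal_matrix(weights_override)
        return [self.classes[i] for i in np.argmax(m, axis=1)]


# -- transition-model context -------------------------------------------------


class _Context:
    """Caches applicability, selection rows, and hazards per (class, elapsed)."""

    def __init__(self, domain: Domain, durations: Mapping, selection: SelectionModel):
        self.domain = domain
        self.durations = durations
        self.selection = selection
        self._trans: dict = {}
        self._hazard: dict = {}
        self.action_classes = {a.id: a.class_label for a in domain.ground}
        self.action_classes[INIT_ACTION_ID] = WAIT_CLASS

    def transitions(self, state):
        """Positive-probability rows: tuples (action, successor, log_prob)."""
        row = self._trans.get(state)
        if row is None:
            dist = selection_distribution(self.domain, self.selection, state)
            row = tuple(
                (a, apply_action(self.domain, state, a), math.log(p))
                for a, p in dist.items()
                if p > 0.0
            )
            self._trans[state] = row
        return row

    def hazard(self, class_label, elapsed, step) -> float:
        key = (class_label, round(elapsed, 9), round(step, 9))
        q = self._hazard.get(key)
        if q is None:
            q = float(duration_hazard(self.durations[class_label], max(elapsed, 0.0), step))
            self._hazard[key] = q
        return q


def _expand(belief_entries, belief_logw, t_cur, t_next, ctx: _Context) -> dict:
    """One prediction step: {successor InferenceState: [(pred_idx, log_trans)]}."""
    step = t_next - t_cur
    if step <= 0:
        raise ValueError("t_next must exceed the belief time")
    expanded: dict = {}
    for i, (x, lw) in enumerate(zip(belief_entries, belief_logw)):
        if lw == _NEG_INF:
            continue
        q = ctx.hazard(ctx.action_classes[x.action_id], t_cur - x.st, step)
        if q < 1.0:
            expanded.setdefault(x, []).append((i, math.log1p(-q)))
        if q > 0.0:
            lq = math.log(q)
            for a, succ, lp in ctx.transitions(x.state):
                key = InferenceState(succ, a.id, t_next)
                expanded.setdefault(key, []).append((i, lq + lp))
    return expanded


def _prior_from_expansion(expanded: dict, belief_logw):
    entries = list(expanded.keys())
    logw = np.array(
        [logsumexp([belief_logw[i] + lt for i, lt in expanded[x]]) for x in entries]
    )
    return entries, logw


def _obs_loglik(obs_model, obs, entries, ctx: _Context) -> np.ndarray:
    if getattr(obs_model, "keyed_by", "class") == "class":
        vec = obs_model.log_likelihood_vector(obs)
        cidx = obs_model.class_index
        return np.array(
            [vec[cidx[ctx.action_classes[x.action_id]]] for x in entries]
        )
    cache: dict = {}
    out = np.empty(len(entries))
    for i, x in enumerate(entries):
        ll = cache.get(x.state)
        if ll is None:
            ll = obs_model.log_likelihood_state(obs, x.state)
            cache[x.state] = ll
        out[i] = ll
    return out


# -- public single-step operations --------------------------------------------


def mf_predict(belief: Belief, t_next: float, domain: Domain, durations: Mapping,
               selection: SelectionModel) -> Belief:
    """Expand a belief to the next timestamp (uncorrected prior, merged)."""
    ctx = _Context(domain, durations, selection)
    expanded = _expand(belief.entries, belief.log_weights, belief.time, t_next, ctx)
    entries, logw = _prior_from_expansion(expanded, belief.log_weights)
    return Belief(entries, logw, time=t_next, capacity=belief.capacity)


def mf_update(expanded: Belief, obs, obs_model, K: int,
              domain: Domain | None = None) -> Belief:
    """Bayes update + top-K pruning + renormalisation of an expanded belief.

    For class-keyed observation models, ``domain`` supplies the action ->
    class map (the running filter passes its own context instead).
    """
    if not expanded.entries:
        raise ValueError("empty expanded belief")
    ctx = None
    if getattr(obs_model, "keyed_by", "class") == "class":
        if domain is None:
            raise ValueError("class-keyed update requires the domain (action->class map)")

        class _Shim:
            action_classes = {a.id: a.class_label for a in domain.ground}

        _Shim.action_classes[INIT_ACTION_ID] = WAIT_CLASS
        ctx = _Shim()
    ll = _obs_loglik(obs_model, obs, expanded.entries, ctx)
    post = expanded.log_weights + ll
    kept, logw, _, _ = _prune(expanded.entries, post, ll, None, K, expanded)
    return Belief(kept, logw, time=expanded.time, capacity=K)


def _prune(entries, post, ll, expanded_links, K, prior_belief):
    """Sort by posterior weight (ties: canonical order), keep K, renormalise."""
    finite = [i for i, v in enumerate(post) if v > _NEG_INF]
    if not finite:
        best = sorted(range(len(entries)), key=lambda i: -prior_belief.log_weights[i])[:5]
        diag = [(entries[i], float(prior_belief.log_weights[i])) for i in best]
        raise ObservationImpossibleError(
            f"observation impossible under model; best prior entries: {diag}"
        )
    order = sorted(finite, key=lambda i: (-post[i], _canonical_key(entries[i])))[:K]
    kept = [entries[i] for i in order]
    kept_post = np.array([post[i] for i in order])
    kept_ll = np.array([ll[i] for i in order]) if ll is not None else None
    logw = kept_post - logsumexp(kept_post)
    return kept, logw, kept_ll, order


# -- full filter runs ----------------------------------------------------------


def _resolve_timestamps(observations, timestamps, frame_rate):
    n = len(observations)
    if timestamps is None:
        timestamps = np.arange(n) / float(frame_rate)
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != n:
        raise ValueError("timestamps and observations disagree in length")
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return timestamps


def _classes_of(domain, obs_model):
    if getattr(obs_model, "keyed_by", "class") == "class":
        return tuple(obs_model.classes)
    return domain.classes


def mf_filter(domain: Domain, durations: Mapping, selection: SelectionModel, obs_model,
              observations: Sequence, K: int, timestamps=None, frame_rate: float = 1.0,
              keep_links: bool = True) -> FilterResult:
    """Marginal filtering of an observation sequence.

    The belief is initialised as a point mass on the initial LTS state
    executing a virtual start action of the wait class, one inter-frame
    interval before the first observation; each step alternates prediction
    (hazard-branched expansion, duplicate merging) and Bayes update with
    top-K pruning.  Lattice links between retained entries are recorded for
    :func:`mf_smooth` and :func:`mf_viterbi`.
    """
    timestamps = _resolve_timestamps(observations, timestamps, frame_rate)
    dt0 = timestamps[1] - timestamps[0] if len(timestamps) > 1 else 1.0 / frame_rate
    ctx = _Context(domain, durations, selection)
    init = InferenceState(domain.initial, INIT_ACTION_ID, float(timestamps[0] - dt0))
    entries, logw = [init], np.zeros(1)
    t_cur = init.st
    steps: list[StepRecord] = []
    evidence = np.empty(len(observations))
    for k, (t_next, obs) in enumerate(zip(timestamps, observations)):
        expanded = _expand(entries, logw, t_cur, float(t_next), ctx)
        exp_entries, prior_logw = _prior_from_expansion(expanded, logw)
        ll = _obs_loglik(obs_model, obs, exp_entries, ctx)
        post = prior_logw + ll
        evidence[k] = logsumexp(post)  # recorded before pruning
        kept, kept_logw, kept_ll, order = _prune(
            exp_entries, post, ll, None, K, Belief(exp_entries, prior_logw, float(t_next))
        )
        links = []
        if keep_links:
            pos = {exp_entries[i]: j for j, i in enumerate(order)}
            for x, contribs in expanded.items():
                j = pos.get(x)
                if j is None:
                    continue
                merged: dict = {}
                for i, lt in contribs:
                    merged[i] = lt if i not in merged else float(np.logaddexp(merged[i], lt))
                links.extend((i, j, lt) for i, lt in sorted(merged.items()))
        steps.append(StepRecord(kept, kept_logw, kept_ll, links))
        entries, logw, t_cur = kept, kept_logw, float(t_next)
    return FilterResult(
        mode="marginal",
        classes=_classes_of(domain, obs_model),
        timestamps=timestamps,
        steps=steps,
        log_evidence_increments=evidence,
        units=K,
        init_entry=init,
        action_classes=dict(ctx.action_classes),
    )


def mf_smooth(result: FilterResult) -> list:
    """Approximate marginal smoothing on the retained lattice.

    Backward recursion restricted to the pruned supports; returns one
    normalised log-weight array per step (aligned with ``step.entries``).
    The final step's smoothed weights equal the filtered ones.
    """
    if result.mode != "marginal":
        raise ValueError("smoothing requires a marginal-filter result")
    T = len(result.steps)
    log_beta = [None] * T
    log_beta[T - 1] = np.zeros(len(result.steps[T - 1].entries))
    for k in range(T - 2, -1, -1):
        cur, nxt = result.steps[k], result.steps[k + 1]
        acc = [[] for _ in cur.entries]
        for i, j, lt in nxt.links:
            acc[i].append(lt + nxt.log_lik[j] + log_beta[k + 1][j])
        log_beta[k] = np.array([logsumexp(a) if a else _NEG_INF for a in acc])
    out = []
    for k in range(T):
        lw = result.steps[k].log_weights + log_beta[k]
        out.append(lw - logsumexp(lw))
    return out


def mf_viterbi(result: FilterResult):
    """MAP inference-state path through the retained lattice (max-product).

    Returns ``(states, classes)``: the most probable sequence of inference
    states and its per-step action-class labels.  Ties break toward the
    lower-index (higher filtered weight, then canonical order) entry.
    """
    if result.mode != "marginal":
        raise ValueError("Viterbi requires a marginal-filter result")
    T = len(result.steps)
    deltas, backs = [], []
    for k in range(T):
        step = result.steps[k]
        delta = np.full(len(step.entries), _NEG_INF)
        back = np.full(len(step.entries), -1, dtype=int)
        for i, j, lt in sorted(step.links, key=lambda l: (l[1], l[0])):
            base = 0.0 if k == 0 else deltas[k - 1][i]
            cand = base + lt + step.log_lik[j]
            if cand > delta[j]:
                delta[j] = cand
                back[j] = i
        deltas.append(delta)
        backs.append(back)
    j = int(np.argmax(deltas[T - 1]))
    path = [None] * T
    for k in range(T - 1, -1, -1):
        path[k] = result.steps[k].entries[j]
        j = int(backs[k][j])
    classes = [result.action_classes[x.action_id] for x in path]
    return path, classes


# -- particle filter -----------------------------------------------------------


def _systematic_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = len(weights)
    positions = (np.arange(n) + rng.random()) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


def pf_filter(domain: Domain, durations: Mapping, selection: SelectionModel, obs_model,
              observations: Sequence, N: int, ess_threshold: float | None = None,
              seed: int | np.random.Generator = 0, timestamps=None,
              frame_rate: float = 1.0) -> FilterResult:
    """Bootstrap particle filtering with ESS-triggered systematic resampling.

    Each particle is an inference-state triple; propagation samples the
    (terminate?, next action) branch from the transition model, weights are
    proportional to the observation likelihood, and systematic resampling
    fires when the effective sample size 1/sum(w^2) drops below
    ``ess_threshold`` (default N/2).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if ess_threshold is None:
        ess_threshold = N / 2.0
    if not 1 <= ess_threshold <= N:
        raise ValueError("ess_threshold must lie in [1, N]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timestamps = _resolve_timestamps(observations, timestamps, frame_rate)
    dt0 = timestamps[1] - timestamps[0] if len(timestamps) > 1 else 1.0 / frame_rate
    ctx = _Context(domain, durations, selection)

    # lazily indexed state table; per-state cached sampling rows
    state_list = [domain.initial]
    state_pos = {domain.initial: 0}
    rows: dict = {}  # state_idx -> (action_ids, succ_idx array, probs array)

    def row_for(si: int):
        row = rows.get(si)
        if row is None:
            trans = ctx.transitions(state_list[si])
            aids, succs, probs = [], [], []
            for a, succ, lp in trans:
                j = state_pos.get(succ)
                if j is None:
                    j = len(state_list)
                    state_pos[succ] = j
                    state_list.append(succ)
                aids.append(a.id)
                succs.append(j)
                probs.append(math.exp(lp))
            row = (aids, np.asarray(succs), np.asarray(probs) / np.sum(probs))
            rows[si] = row
        return row

    aclass = ctx.action_classes
    class_list = sorted({c for c in aclass.values()})
    s_idx = np.zeros(N, dtype=int)
    a_ids = np.array([INIT_ACTION_ID] * N, dtype=object)
    st = np.full(N, float(timestamps[0] - dt0))
    logw = np.full(N, -math.log(N))
    t_cur = float(timestamps[0] - dt0)

    steps: list[StepRecord] = []
    evidence = np.empty(len(observations))
    for k, (t_next, obs) in enumerate(zip(timestamps, observations)):
        t_next = float(t_next)
        step_dt = t_next - t_cur
        # hazard per particle, grouped by running class
        q = np.empty(N)
        part_classes = np.array([aclass[a] for a in a_ids], dtype=object)
        for c in class_list:
            mask = part_classes == c
            if mask.any():
                q[mask] = duration_hazard(durations[c], np.maximum(t_cur - st[mask], 0.0), step_dt)
        term = rng.random(N) < q
        pre_idx = s_idx.copy()  # masks must reference pre-transition states
        for si in np.unique(pre_idx[term]):
            mask = term & (pre_idx == si)
            aids, succs, probs = row_for(int(si))
            draws = rng.choice(len(aids), size=int(mask.sum()), p=probs)
            a_ids[mask] = np.array(aids, dtype=object)[draws]
            s_idx[mask] = succs[draws]
            st[mask] = t_next
        # weighting
        if getattr(obs_model, "keyed_by", "class") == "class":
            vec = obs_model.log_likelihood_vector(obs)
            cmap = {c: vec[obs_model.class_index[c]] for c in obs_model.classes}
            ll = np.array([cmap[aclass[a]] for a in a_ids])
        else:
            uniq = np.unique(s_idx)
            smap = {int(si): obs_model.log_likelihood_state(obs, state_list[int(si)])
                    for si in uniq}
            ll = np.array([smap[int(si)] for si in s_idx])
        logw = logw + ll
        z = logsumexp(logw)
        if z == _NEG_INF:
            raise ObservationImpossibleError(
                f"all particle weights vanished at step {k} (t={t_next})"
            )
        evidence[k] = z
        logw = logw - z
        w = np.exp(logw)
        ess = 1.0 / float(np.sum(w * w))
        # aggregate distinct inference states for the step record
        agg: dict = {}
        for i in range(N):
            key = (int(s_idx[i]), a_ids[i], float(st[i]))
            agg[key] = agg.get(key, 0.0) + w[i]
        entries = [InferenceState(state_list[si], aid, t) for (si, aid, t) in agg]
        wts = np.array(list(agg.values()))
        with np.errstate(divide="ignore"):
            steps.append(StepRecord(entries, np.log(wts), None, [], ess=ess))
        if ess < ess_threshold:
            idx = _systematic_resample(w, rng)
            s_idx, a_ids, st = s_idx[idx], a_ids[idx], st[idx]
            logw = np.full(N, -math.log(N))
        t_cur = t_next
    return FilterResult(
        mode="particle",
        classes=_classes_of(domain, obs_model),
        timestamps=timestamps,
        steps=steps,
        log_evidence_increments=evidence,
        units=N,
        init_entry=InferenceState(domain.initial, INIT_ACTION_ID, float(timestamps[0] - dt0)),
        action_classes=dict(aclass),
    )


# -- point estimates, predicate tracks, accounting -----------------------------


def class_marginals(entries, weights, action_classes, classes) -> dict:
    """Marginal class distribution of one step's weighted entry set."""
    out = {c: 0.0 for c in classes}
    for x, w in zip(entries, weights):
        out[action_classes[x.action_id]] += float(w)
    return out


def point_estimate(marginals: Mapping) -> str:
    """Most probable class; ties break by class order (deterministic)."""
    best, best_p = None, -1.0
    for c, p in marginals.items():
        if p > best_p:
            best, best_p = c, p
    return best


def predicate_track(result: FilterResult, predicate: Callable, mode: str = "filtered",
                    smoothed=None) -> np.ndarray:
    """Per-step probability that the LTS state satisfies ``predicate``."""
    if mode not in ("filtered", "smoothed"):
        raise ValueError("mode must be 'filtered' or 'smoothed'")
    if mode == "smoothed" and smoothed is None:
        smoothed = mf_smooth(result)
    out = np.zeros(len(result.steps))
    cache: dict = {}
    for k, step in enumerate(result.steps):
        lw = step.log_weights if mode == "filtered" else smoothed[k]
        w = np.exp(lw)
        for x, wi in zip(step.entries, w):
            hit = cache.get(x.state)
            if hit is None:
                hit = bool(predicate(x.state))
                cache[x.state] = hit
            if hit:
                out[k] += wi
    # guard against accumulated rounding pushing a certain probability past 1
    return np.clip(out, 0.0, 1.0)


def representation_accounting(result: FilterResult) -> pd.DataFrame:
    """Distinct LTS / inference states per step, normalised by capacity.

    SpU = #S / units, XpU = #X / units, XpS = #X / #S; units is K for the
    marginal filter and N for the particle filter.
    """
    rows = []
    for k, step in enumerate(result.steps):
        n_x = len(step.entries)
        n_s = len({x.state for x in step.entries})
        rows.append(
            {
                "step": k,
                "n_states": n_s,
                "n_x": n_x,
                "spu": n_s / result.units,
                "xpu": n_x / result.units,
                "xps": n_x / n_s if n_s else math.nan,
            }
        )
    return pd.DataFrame(rows)
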