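"""Independent reference implementations used to check the package.

Everything here is written from the model definitions directly, in plain
linear-probability Python with dictionaries and explicit loops — a different
code path (and mostly different arithmetic) from the log-space, cached,
vectorised implementations under test.
"""

from __future__ import annotations

import math

import numpy as np

from cssmkit.domain import applicable_actions, apply_action
from cssmkit.inference import INIT_ACTION_ID
from cssmkit.domain import WAIT_CLASS


# -- selection and hazard (recomputed from first principles) -------------------


def selection_row(domain, selection, state):
    """{GroundAction: prob} recomputed directly from the model definition."""
    actions = applicable_actions(domain, state)
    if selection.kind == "uniform":
        return {a: 1.0 / len(actions) for a in actions}
    if selection.kind == "tabular":
        row = selection.table[state]
        total = sum(float(row[a.id]) for a in actions)
        return {a: float(row[a.id]) / total for a in actions}
    hs = {}
    for a in actions:
        h = selection.h(apply_action(domain, state, a))
        if math.isinf(h):
            h = selection.h_cap
        hs[a] = h
    if selection.kind == "epsilon_greedy":
        hmin = min(hs.values())
        greedy = [a for a in actions if hs[a] == hmin]
        out = {}
        for a in actions:
            out[a] = selection.epsilon / len(actions)
            if a in greedy:
                out[a] += (1.0 - selection.epsilon) / len(greedy)
        return out
    ws = {a: math.exp(-selection.weight * (hs[a] - min(hs.values()))) for a in actions}
    z = sum(ws.values())
    return {a: w / z for a, w in ws.items()}


def hazard_prob(model, elapsed, step):
    """(F(e+dt) - F(e)) / (1 - F(e)), clipped to [0, 1], from the model cdf."""
    sf = 1.0 - model.cdf(elapsed)
    if sf <= 1e-300:
        return 1.0
    q = (model.cdf(elapsed + step) - model.cdf(elapsed)) / sf
    return min(max(q, 0.0), 1.0)


# -- exact inference over the full inference-state lattice ---------------------


def _obs_prob(obs_model, obs, state, class_label):
    if getattr(obs_model, "keyed_by", "class") == "class":
        idx = list(obs_model.classes).index(class_label)
        return math.exp(float(obs_model.log_likelihood_vector(obs)[idx]))
    return math.exp(obs_model.log_likelihood_state(obs, state))


def exact_filter(domain, durations, selection, obs_model, observations, timestamps):
    """Brute-force exact marginal filter (linear space, dict enumeration).

    Returns (list of {(state, action_id, st): prob} per step, log-evidence
    increments, action_classes map).
    """
    timestamps = [float(t) for t in timestamps]
    dt0 = timestamps[1] - timestamps[0] if len(timestamps) > 1 else 1.0
    aclass = {a.id: a.class_label for a in domain.ground}
    aclass[INIT_ACTION_ID] = WAIT_CLASS
    belief = {(domain.initial, INIT_ACTION_ID, timestamps[0] - dt0): 1.0}
    t_cur = timestamps[0] - dt0
    per_step, log_incr = [], []
    rows = {}

    def row(s):
        if s not in rows:
            rows[s] = [(a, apply_action(domain, s, a), pa)
                       for a, pa in selection_row(domain, selection, s).items()
                       if pa > 0.0]
        return rows[s]

    for t_next, obs in zip(timestamps, observations):
        step = t_next - t_cur
        prior = {}
        for (s, aid, st), p in belief.items():
            q = hazard_prob(durations[aclass[aid]], max(t_cur - st, 0.0), step)
            if q < 1.0:
                key = (s, aid, st)
                prior[key] = prior.get(key, 0.0) + p * (1.0 - q)
            if q > 0.0:
                for a, succ, pa in row(s):
                    key = (succ, a.id, t_next)
                    prior[key] = prior.get(key, 0.0) + p * q * pa
        post = {}
        for (s, aid, st), p in prior.items():
            lik = _obs_prob(obs_model, obs, s, aclass[aid])
            if p * lik > 0.0:
                post[(s, aid, st)] = p * lik
        z = sum(post.values())
        log_incr.append(math.log(z))
        belief = {k: v / z for k, v in post.items()}
        per_step.append(dict(belief))
        t_cur = t_next
    return per_step, np.array(log_incr), aclass


def exact_smooth(domain, durations, selection, obs_model, observations, timestamps):
    """Exact fixed-interval smoothing over the full inference-state lattice."""
    timestamps = [float(t) for t in timestamps]
    aclass = {a.id: a.class_label for a in domain.ground}
    aclass[INIT_ACTION_ID] = WAIT_CLASS
    filtered, _, _ = exact_filter(domain, durations, selection, obs_model,
                                  observations, timestamps)
    T = len(observations)
    rows = {}

    def row(s):
        if s not in rows:
            rows[s] = [(a, apply_action(domain, s, a), pa)
                       for a, pa in selection_row(domain, selection, s).items()
                       if pa > 0.0]
        return rows[s]

    beta = {x: 1.0 for x in filtered[T - 1]}
    smoothed = [None] * T
    smoothed[T - 1] = dict(filtered[T - 1])
    for k in range(T - 2, -1, -1):
        t_cur, t_next = timestamps[k], timestamps[k + 1]
        nxt = filtered[k + 1]
        lik_next = {y: _obs_prob(obs_model, observations[k + 1], y[0], aclass[y[1]])
                    for y in nxt}
        new_beta = {}
        for x in filtered[k]:
            s, aid, st = x
            q = hazard_prob(durations[aclass[aid]], max(t_cur - st, 0.0), t_next - t_cur)
            acc = 0.0
            if q < 1.0 and x in beta and x in nxt:
                acc += (1.0 - q) * lik_next[x] * beta[x]
            if q > 0.0:
                for a, succ, pa in row(s):
                    y = (succ, a.id, t_next)
                    if y in nxt:
                        acc += q * pa * lik_next[y] * beta[y]
            new_beta[x] = acc
        beta = new_beta
        sm = {x: filtered[k][x] * beta[x] for x in filtered[k]}
        z = sum(sm.values())
        smoothed[k] = {x: v / z for x, v in sm.items()}
    return smoothed


def exact_viterbi(domain, durations, selection, obs_model, observations, timestamps):
    """Exhaustive max-product decoding over the full inference-state lattice."""
    timestamps = [float(t) for t in timestamps]
    dt0 = timestamps[1] - timestamps[0] if len(timestamps) > 1 else 1.0
    aclass = {a.id: a.class_label for a in domain.ground}
    aclass[INIT_ACTION_ID] = WAIT_CLASS
    init = (domain.initial, INIT_ACTION_ID, timestamps[0] - dt0)
    delta = {init: 0.0}
    backs = []
    t_cur = init[2]
    rows = {}

    def row(s):
        if s not in rows:
            rows[s] = [(a, apply_action(domain, s, a), pa)
                       for a, pa in selection_row(domain, selection, s).items()
                       if pa > 0.0]
        return rows[s]

    for t_next, obs in zip(timestamps, observations):
        step = t_next - t_cur
        new_delta, back = {}, {}

        def consider(key, val, pred):
            if val > new_delta.get(key, -math.inf):
                new_delta[key] = val
                back[key] = pred

        for (s, aid, st), d in delta.items():
            q = hazard_prob(durations[aclass[aid]], max(t_cur - st, 0.0), step)
            if q < 1.0:
                consider((s, aid, st), d + math.log1p(-q), (s, aid, st))
            if q > 0.0:
                for a, succ, pa in row(s):
                    consider((succ, a.id, t_next),
                             d + math.log(q) + math.log(pa), (s, aid, st))
        for key in list(new_delta):
            lik = _obs_prob(obs_model, obs, key[0], aclass[key[1]])
            if lik > 0.0:
                new_delta[key] += math.log(lik)
            else:
                del new_delta[key]
                del back[key]
        delta = new_delta
        backs.append(back)
        t_cur = t_next
    best = max(delta, key=lambda k: (delta[k],))
    score = delta[best]
    path = [best]
    for back in reversed(backs[1:]):
        path.append(back[path[-1]])
    path.reverse()
    return path, score


def path_log_prob(domain, durations, selection, obs_model, observations,
                  timestamps, path):
    """Log joint probability of one inference-state path (with emissions)."""
    timestamps = [float(t) for t in timestamps]
    dt0 = timestamps[1] - timestamps[0] if len(timestamps) > 1 else 1.0
    aclass = {a.id: a.class_label for a in domain.ground}
    aclass[INIT_ACTION_ID] = WAIT_CLASS
    prev = (domain.initial, INIT_ACTION_ID, timestamps[0] - dt0)
    t_cur = prev[2]
    lp = 0.0
    for (t_next, obs, cur) in zip(timestamps, observations, path):
        s, aid, st = prev
        q = hazard_prob(durations[aclass[aid]], max(t_cur - st, 0.0), t_next - t_cur)
        if cur == prev:
            lp += math.log1p(-q)
        else:
            s2, aid2, st2 = cur
            assert st2 == t_next, "terminating path entries must restart at t_next"
            pa = 0.0
            for a, p in selection_row(domain, selection, s).items():
                if a.id == aid2 and apply_action(domain, s, a) == s2:
                    pa = p
            assert pa > 0.0, "path uses an impossible transition"
            lp += math.log(q) + math.log(pa)
        lp += math.log(_obs_prob(obs_model, obs, cur[0], aclass[cur[1]]))
        prev, t_cur = cur, t_next
    return lp


def class_marginal(step_belief, aclass, classes):
    out = {c: 0.0 for c in classes}
    for (s, aid, st), p in step_belief.items():
        out[aclass[aid]] += p
    return out


def predicate_probability(step_belief, predicate):
    return sum(p for (s, aid, st), p in step_belief.items() if predicate(s))


# -- HMM reference (linear space, scaled) --------------------------------------


def hmm_forward_ref(pi, A, B):
    """B is the (T, C) likelihood matrix; returns (alpha (T,C), log-evidence)."""
    T, C = B.shape
    alpha = np.empty((T, C))
    log_incr = np.empty(T)
    cur = pi * B[0]
    for t in range(T):
        if t > 0:
            cur = (alpha[t - 1] @ A) * B[t]
        z = cur.sum()
        alpha[t] = cur / z
        log_incr[t] = math.log(z)
    return alpha, log_incr


def hmm_smooth_ref(pi, A, B):
    T, C = B.shape
    alpha, _ = hmm_forward_ref(pi, A, B)
    beta = np.ones((T, C))
    for t in range(T - 2, -1, -1):
        b = A @ (B[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    g = alpha * beta
    return g / g.sum(axis=1, keepdims=True)


def hmm_viterbi_brute(pi, A, B):
    """Exhaustive enumeration of all C^T paths (tiny instances only)."""
    import itertools

    T, C = B.shape
    best, best_lp = None, -math.inf
    for path in itertools.product(range(C), repeat=T):
        lp = math.log(pi[path[0]]) if pi[path[0]] > 0 else -math.inf
        lp += math.log(B[0, path[0]]) if B[0, path[0]] > 0 else -math.inf
        for t in range(1, T):
            a = A[path[t - 1], path[t]]
            b = B[t, path[t]]
            if a <= 0 or b <= 0:
                lp = -math.inf
                break
            lp += math.log(a) + math.log(b)
        if lp > best_lp:
            best, best_lp = path, lp
    return list(best), best_lp


# -- sequence metrics ----------------------------------------------------------


def levenshtein_ref(a, b):
    a, b = list(a), list(b)
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[len(b)]


def dtw_ref(a, b):
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            c = 0.0 if a[i - 1] == b[j - 1] else 1.0
            D[i, j] = c + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def jsd_ref(p, q):
    """Jensen-Shannon distance for Bernoulli parameters, direct formula."""

    def kl(a, b):
        acc = 0.0
        for x, y in ((a, b), (1 - a, 1 - b)):
            if x > 0:
                acc += x * math.log2(x / y)
        return acc

    m = 0.5 * (p + q)
    div = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return math.sqrt(max(div, 0.0))


def bfs_distances(edges, sources, n):
    """Unweighted shortest path lengths to the nearest source (reversed BFS)."""
    from collections import deque

    radj = [[] for _ in range(n)]
    for u, v in edges:
        radj[v].append(u)
    dist = [math.inf] * n
    dq = deque()
    for s in sources:
        dist[s] = 0
        dq.append(s)
    while dq:
        v = dq.popleft()
        for u in radj[v]:
            if dist[u] == math.inf:
                dist[u] = dist[v] + 1
                dq.append(u)
    return dist
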