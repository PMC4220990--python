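"""Training-based comparison models: frame-wise QDA and a class-level HMM.

QDA scores each frame independently: posterior proportional to class prior
times the class-conditional Gaussian likelihood.  The HMM adds a first-order
temporal model whose transition matrix is obtained by counting class
transitions in frame-level annotations (optionally with a pseudocount;
the default of 0 mirrors plain frequency counting, at the price of an
explicit dead-end error when an unseen transition is required).  Forward
filtering, forward-backward smoothing, and Viterbi decoding all run in log
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .observations import GaussianClassModel

__all__ = [
    "HmmModel",
    "fit_hmm",
    "qda_predict",
    "hmm_forward",
    "hmm_smooth",
    "hmm_viterbi",
]


@dataclass
class HmmModel:
    """Class-level HMM: initial distribution + row-stochastic transitions."""

    classes: tuple
    initial: np.ndarray  # (C,)
    transition: np.ndarray  # (C, C), rows sum to 1
    obs_model: GaussianClassModel | None = None

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if abs(self.initial.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1")
        rs = self.transition.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > 1e-12):
            raise ValueError("transition rows must sum to 1")
        self.class_index = {c: i for i, c in enumerate(self.classes)}
        with np.errstate(divide="ignore"):
            self.log_initial = np.log(self.initial)
            self.log_transition = np.log(self.transition)


def fit_hmm(sequences: Sequence[Sequence], pseudocount: float = 0.0,
            class_alphabet: Sequence | None = None,
            obs_model: GaussianClassModel | None = None) -> HmmModel:
    """Count class-transition frequencies over annotation sequences.

    ``transition(i, j) propto count(i -> j) + pseudocount``; the initial
    distribution counts first-frame classes the same way.
    """
    if not sequences:
        raise ValueError("need at least one annotation sequence")
    classes = set(class_alphabet or ())
    for seq in sequences:
        classes.update(seq)
    classes = tuple(sorted(classes))
    if not classes:
        raise ValueError("empty class alphabet")
    idx = {c: i for i, c in enumerate(classes)}
    C = len(classes)
    trans = np.full((C, C), float(pseudocount))
    init = np.full(C, float(pseudocount))
    for seq in sequences:
        seq = list(seq)
        if not seq:
            continue
        init[idx[seq[0]]] += 1.0
        for a, b in zip(seq[:-1], seq[1:]):
            trans[idx[a], idx[b]] += 1.0
    init = init / init.sum()
    row_sums = trans.sum(axis=1, keepdims=True)
    # rows never observed (and pseudocount 0) fall back to self-absorption
    dead = row_sums[:, 0] == 0.0
    trans[dead] = np.eye(C)[dead]
    row_sums = trans.sum(axis=1, keepdims=True)
    trans = trans / row_sums
    return HmmModel(classes=classes, initial=init, transition=trans, obs_model=obs_model)


def _loglik_matrix(model, frames) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 2:
        raise ValueError("frames must be 2-D")
    if model.obs_model is not None and frames.shape[1] == model.obs_model.dim:
        ll = model.obs_model.log_likelihood_matrix(frames)
        if tuple(model.obs_model.classes) != tuple(model.classes):
            cols = [model.obs_model.class_index[c] for c in model.classes]
            ll = ll[:, cols]
        return ll
    if frames.shape[1] == len(model.classes):
        return frames  # pre-computed per-frame log-likelihoods
    raise ValueError("frames must be feature rows (with obs_model set) or a (T, C) loglik matrix")


def qda_predict(model: GaussianClassModel, frames):
    """Frame-wise Bayes rule: posterior ∝ prior × Gaussian likelihood.

    Returns ``(posterior (T, C), point estimates)``; argmax ties break
    toward the first class in the model's class order.
    """
    ll = model.log_likelihood_matrix(np.asarray(frames, dtype=float))
    with np.errstate(divide="ignore"):
        lp = ll + np.log(model.priors)
    post = np.exp(lp - logsumexp(lp, axis=1, keepdims=True))
    estimates = [model.classes[i] for i in np.argmax(post, axis=1)]
    return post, estimates


def hmm_forward(model: HmmModel, frames):
    """Log-space forward filtering.

    Returns ``(log_filtered (T, C), log_evidence_increments (T,))``, the
    per-step normalised forward distributions and normalisation constants.
    """
    return _forward_ll(model, _loglik_matrix(model, frames))


def _forward_ll(model: HmmModel, ll: np.ndarray):
    T, C = ll.shape
    log_alpha = np.empty((T, C))
    incr = np.empty(T)
    cur = model.log_initial + ll[0]
    for t in range(T):
        if t > 0:
            cur = logsumexp(log_alpha[t - 1][:, None] + model.log_transition, axis=0) + ll[t]
        z = logsumexp(cur)
        if z == -math.inf:
            raise ValueError(f"zero-probability dead end at frame {t}")
        log_alpha[t] = cur - z
        incr[t] = z
    return log_alpha, incr


def hmm_smooth(model: HmmModel, frames):
    """Log-space forward-backward; returns normalised log smoothing (T, C)."""
    ll = _loglik_matrix(model, frames)
    log_alpha, _ = _forward_ll(model, ll)
    T, C = ll.shape
    log_beta = np.zeros((T, C))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(
            model.log_transition + (ll[t + 1] + log_beta[t + 1])[None, :], axis=1
        )
    lg = log_alpha + log_beta
    return lg - logsumexp(lg, axis=1, keepdims=True)


def hmm_viterbi(model: HmmModel, frames):
    """Log-space Viterbi decoding; returns the MAP class-label sequence."""
    ll = _loglik_matrix(model, frames)
    T, C = ll.shape
    delta = model.log_initial + ll[0]
    back = np.zeros((T, C), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + model.log_transition
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(C)] + ll[t]
        if np.all(delta == -math.inf):
            raise ValueError(f"zero-probability dead end at frame {t}")
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return [model.classes[i] for i in path]
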