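"""Scoring of estimated label sequences and predicate probability tracks.

Frame-level agreement is summarised in a confusion matrix (accuracy,
per-class precision/recall/F1, Cohen's kappa).  Predicate tracks — per-step
Bernoulli parameters — are compared by the Jensen-Shannon *distance* (the
square root of the base-2 Jensen-Shannon divergence, so the range is
[0, 1]) and by thresholded accuracy.  Sequence structure is compared on
run-collapsed label sequences by unit-cost Levenshtein distance and by
dynamic time warping with 0-1 local cost, plus auxiliary counts (error
probability, run-count difference, and a combined Euclidean score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = [
    "ConfusionMatrix",
    "accuracy",
    "per_class",
    "cohens_kappa",
    "jsd",
    "mean_jsd",
    "predicate_accuracy",
    "collapse_runs",
    "edit_distance",
    "dtw_distance",
    "aux_metrics",
    "MetricReport",
    "score_labels",
]


@dataclass
class ConfusionMatrix:
    """Counts n(true, estimated) over a shared class alphabet."""

    classes: tuple
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be square over the class alphabet")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_sequences(cls, truth: Sequence, estimate: Sequence,
                       classes: Sequence | None = None) -> "ConfusionMatrix":
        truth, estimate = list(truth), list(estimate)
        if len(truth) != len(estimate):
            raise ValueError("truth and estimate disagree in length")
        classes = tuple(sorted(set(classes or ()) | set(truth) | set(estimate)))
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for a, b in zip(truth, estimate):
            counts[idx[a], idx[b]] += 1
        return cls(classes=classes, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of frames on the diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/recall/F1 with the 0/0 -> 0 convention (flagged)."""
    tp = np.diag(cm.counts).astype(float)
    col = cm.counts.sum(axis=0).astype(float)
    row = cm.counts.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    return pd.DataFrame(
        {
            "class": cm.classes,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": row.astype(int),
            "undefined": (col == 0) | (row == 0),
        }
    )


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement from the confusion-matrix marginals.

    kappa = (p_o - p_e) / (1 - p_e); the degenerate case p_e = 1 (all mass
    in a single cell of both marginals) is defined as 0.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / n
    p_e = float(cm.counts.sum(axis=0) @ cm.counts.sum(axis=1)) / (n * n)
    if abs(1.0 - p_e) < 1e-15:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def jsd(p: float, q: float) -> float:
    """Jensen-Shannon distance between Bernoulli(p) and Bernoulli(q).

    Square root of the base-2 Jensen-Shannon divergence; symmetric, in
    [0, 1], with the 0*log(0) = 0 convention.
    """
    for v in (p, q):
        if not 0.0 <= v <= 1.0:
            raise ValueError("Bernoulli parameters must lie in [0, 1]")
    with np.errstate(invalid="ignore"):  # identical inputs can yield sqrt(-0)
        d = float(jensenshannon([p, 1.0 - p], [q, 1.0 - q], base=2))
    return 0.0 if math.isnan(d) else d


def mean_jsd(track_p: Sequence[float], track_q: Sequence[float]) -> float:
    """Mean Jensen-Shannon distance over aligned probability tracks."""
    p = np.asarray(track_p, dtype=float)
    q = np.asarray(track_q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("tracks disagree in length")
    return float(np.mean([jsd(a, b) for a, b in zip(p, q)]))


def predicate_accuracy(track: Sequence[float], truth_track: Sequence[float]) -> float:
    """Agreement after thresholding both tracks at probability >= 0.5."""
    p = np.asarray(track, dtype=float)
    q = np.asarray(truth_track, dtype=float)
    if p.shape != q.shape:
        raise ValueError("tracks disagree in length")
    return float(np.mean((p >= 0.5) == (q >= 0.5)))


def collapse_runs(labels: Sequence) -> list:
    """Merge consecutive duplicate labels into single run symbols."""
    out = []
    for x in labels:
        if not out or out[-1] != x:
            out.append(x)
    return out


def edit_distance(truth_runs: Sequence, est_runs: Sequence) -> int:
    """Unit-cost Levenshtein distance between run-collapsed label sequences."""
    alphabet = {}
    for x in list(truth_runs) + list(est_runs):
        if x not in alphabet:
            alphabet[x] = chr(0x100 + len(alphabet))
    a = "".join(alphabet[x] for x in truth_runs)
    b = "".join(alphabet[x] for x in est_runs)
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def dtw_distance(truth_frames: Sequence, est_frames: Sequence) -> float:
    """Dynamic time warping with 0-1 local cost and unconstrained window."""
    a, b = list(truth_frames), list(est_frames)
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    prev = np.empty(m + 1)
    cur = np.empty(m + 1)
    prev[:] = np.inf
    prev[0] = 0.0
    for i in range(1, n + 1):
        cur[:] = np.inf
        ai = a[i - 1]
        cost = np.array([0.0 if ai == b[j] else 1.0 for j in range(m)])
        for j in range(1, m + 1):
            cur[j] = cost[j - 1] + min(prev[j], cur[j - 1], prev[j - 1])
        prev, cur = cur, prev
    return float(prev[m])


def aux_metrics(truth: Sequence, estimate: Sequence) -> dict:
    """Error probability, run-count difference, and combined Euclidean score.

    - ``error_probability`` = 1 - frame accuracy
    - ``delta_actions`` = |#runs(estimate) - #runs(truth)|
    - ``combined`` = Euclidean norm of (error probability, delta_actions
      normalised by #runs(truth)) — a reconstruction of the two-component
      distance, not a canonical formula.
    """
    truth, estimate = list(truth), list(estimate)
    if len(truth) != len(estimate):
        raise ValueError("truth and estimate disagree in length")
    pe = float(np.mean([a != b for a, b in zip(truth, estimate)]))
    rt, re = len(collapse_runs(truth)), len(collapse_runs(estimate))
    delta = abs(re - rt)
    combined = math.hypot(pe, delta / rt if rt else math.inf)
    return {"error_probability": pe, "delta_actions": delta, "combined": combined}


@dataclass
class MetricReport:
    """Bundle of sequence metrics for one (truth, estimate) pair."""

    confusion: ConfusionMatrix
    accuracy: float
    kappa: float
    edit_distance: int
    dtw: float
    error_probability: float
    delta_actions: int
    combined: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "edit_distance": self.edit_distance,
            "dtw": self.dtw,
            "error_probability": self.error_probability,
            "delta_actions": self.delta_actions,
            "combined": self.combined,
        }


def score_labels(truth: Sequence, estimate: Sequence,
                 classes: Sequence | None = None) -> MetricReport:
    """All frame- and sequence-level metrics for a label-sequence pair."""
    cm = ConfusionMatrix.from_sequences(truth, estimate, classes)
    aux = aux_metrics(truth, estimate)
    return MetricReport(
        confusion=cm,
        accuracy=accuracy(cm),
        kappa=cohens_kappa(cm),
        edit_distance=edit_distance(collapse_runs(truth), collapse_runs(estimate)),
        dtw=dtw_distance(truth, estimate),
        error_probability=aux["error_probability"],
        delta_actions=aux["delta_actions"],
        combined=aux["combined"],
    )
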