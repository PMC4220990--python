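"""Observation front-end and likelihood models.

Two observation channels feed the filters:

- continuous feature vectors (windowed statistics of multichannel signals,
  optionally PCA-reduced) scored by class-conditional multivariate
  Gaussians with unconstrained covariance, and
- categorical location observations (tuples of place symbols read off
  selected slots of the true state) scored by a per-slot confusion model.

The module also provides the synthetic generators used throughout the test
harness: class-conditional Gaussian frames with an optional within-run
drift (to emulate non-i.i.d. real sensor runs) and the *scrambling*
operation — a within-class permutation of frames that restores the i.i.d.
assumption while leaving the label sequence untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .domain import Domain

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "PcaTransform",
    "pca_reduce",
    "GaussianClassModel",
    "fit_gaussian_models",
    "log_likelihood",
    "LocationSensorModel",
    "generate_location_observations",
    "scramble",
    "ClassObservationSpec",
    "make_class_spec",
    "generate_observations",
]

FEATURE_NAMES = ("mean", "var", "skew", "kurt", "peak", "energy")


def extract_features(signals, window: int, overlap: float = 0.75, sampling_rate: float = 120.0):
    """Windowed per-channel statistics of a multichannel sampled stream.

    For every window and channel: mean, variance, skewness, excess kurtosis,
    peak (max absolute value), and energy (mean of squared samples).  Skew
    and kurtosis of a zero-variance window are 0 by convention.  Frame
    timestamps sit at window centers.

    Returns ``(timestamps, features)`` with features of shape
    ``(n_frames, 6 * n_channels)``, channel-major.
    """
    x = np.asarray(signals, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, c = x.shape
    if window < 4:
        raise ValueError("window must be >= 4")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    hop = max(1, int(round(window * (1.0 - overlap))))
    if n < window:
        raise ValueError(f"stream of {n} samples is shorter than one window ({window})")
    starts = np.arange(0, n - window + 1, hop)
    feats = np.empty((len(starts), 6 * c))
    for k, s in enumerate(starts):
        w = x[s : s + window]
        mean = w.mean(axis=0)
        var = w.var(axis=0)
        sd = np.sqrt(var)
        centered = w - mean
        with np.errstate(divide="ignore", invalid="ignore"):
            skew = np.where(sd > 0, (centered**3).mean(axis=0) / np.where(sd > 0, sd, 1) ** 3, 0.0)
            kurt = np.where(
                var > 0, (centered**4).mean(axis=0) / np.where(var > 0, var, 1) ** 2 - 3.0, 0.0
            )
        peak = np.abs(w).max(axis=0)
        energy = (w**2).mean(axis=0)
        feats[k] = np.column_stack([mean, var, skew, kurt, peak, energy]).ravel()
    timestamps = (starts + (window - 1) / 2.0) / sampling_rate
    return timestamps, feats


@dataclass
class PcaTransform:
    """Serializable standardize-then-project transform."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (k, d)
    explained_variance_ratio: np.ndarray

    def apply(self, frames) -> np.ndarray:
        z = (np.asarray(frames, dtype=float) - self.mean) / self.scale
        return z @ self.components.T

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }

    @classmethod
    def from_dict(cls, data) -> "PcaTransform":
        return cls(*(np.asarray(data[k], dtype=float) for k in
                     ("mean", "scale", "components", "explained_variance_ratio")))

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "PcaTransform":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def pca_reduce(frames, k: int, standardize: bool = True):
    """Project frames onto the ``k`` largest-eigenvalue principal components.

    Features are standardised (zero mean, unit variance over the fit set)
    before the eigendecomposition unless ``standardize=False``.
    """
    x = np.asarray(frames, dtype=float)
    if x.ndim != 2:
        raise ValueError("frames must be 2-D (n_frames, n_features)")
    if k > x.shape[1]:
        raise ValueError("k exceeds the feature dimension")
    if x.shape[0] < k + 1:
        raise ValueError("need at least k+1 frames")
    sd = x.std(axis=0)
    if np.any(sd == 0) and standardize:
        constant = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"zero-variance features at indices {constant}")
    scaler = StandardScaler(with_std=standardize)
    z = scaler.fit_transform(x)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(z)
    transform = PcaTransform(
        mean=scaler.mean_,
        scale=scaler.scale_ if standardize else np.ones(x.shape[1]),
        components=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    return transform, scores


@dataclass
class GaussianClassModel:
    """Class-conditional multivariate normals with full covariance + priors."""

    classes: tuple
    means: np.ndarray  # (C, d)
    covariances: np.ndarray  # (C, d, d)
    priors: np.ndarray  # (C,)
    unseen: tuple = ()

    keyed_by = "class"

    def __post_init__(self):
        self._chol = np.linalg.cholesky(self.covariances)
        d = self.means.shape[1]
        logdet = 2.0 * np.log(np.diagonal(self._chol, axis1=1, axis2=2)).sum(axis=1)
        self._const = -0.5 * (d * math.log(2.0 * math.pi) + logdet)
        self.class_index = {c: i for i, c in enumerate(self.classes)}

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def log_likelihood_vector(self, frame) -> np.ndarray:
        """Per-class Gaussian log-density of a single frame."""
        x = np.asarray(frame, dtype=float)
        if x.shape[-1] != self.dim:
            raise ValueError(f"frame dimension {x.shape[-1]} != model dimension {self.dim}")
        diff = x - self.means  # (C, d)
        out = np.empty(len(self.classes))
        for i in range(len(self.classes)):
            y = np.linalg.solve(self._chol[i], diff[i])
            out[i] = self._const[i] - 0.5 * float(y @ y)
        return out

    def log_likelihood_matrix(self, frames) -> np.ndarray:
        """(T, C) log-densities for a frame sequence (vectorised per class)."""
        x = np.asarray(frames, dtype=float)
        out = np.empty((x.shape[0], len(self.classes)))
        for i in range(len(self.classes)):
            diff = x - self.means[i]
            y = np.linalg.solve(self._chol[i], diff.T)  # (d, T)
            out[:, i] = self._const[i] - 0.5 * np.sum(y * y, axis=0)
        return out


def fit_gaussian_models(frames, labels, regularization: float | None = None,
                        class_alphabet: Sequence | None = None) -> GaussianClassModel:
    """Per-class MLE mean/covariance with a ridge term; priors = frequencies.

    ``regularization`` defaults to ``1e-6 * trace(cov) / dim`` per class, which
    guarantees positive-definite covariances.  Alphabet classes without
    frames get a unit-covariance placeholder with prior 0 and are flagged in
    ``model.unseen``.
    """
    x = np.asarray(frames, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("frames and labels disagree in length")
    classes = tuple(sorted(set(labels) | set(class_alphabet or ())))
    d = x.shape[1]
    means = np.zeros((len(classes), d))
    covs = np.tile(np.eye(d), (len(classes), 1, 1))
    priors = np.zeros(len(classes))
    unseen = []
    for i, c in enumerate(classes):
        mask = labels == c
        n = int(mask.sum())
        if n == 0:
            unseen.append(c)
            continue
        xi = x[mask]
        means[i] = xi.mean(axis=0)
        cov = np.cov(xi.T, bias=True).reshape(d, d) if n > 1 else np.zeros((d, d))
        ridge = regularization
        if ridge is None:
            tr = float(np.trace(cov))
            ridge = 1e-6 * (tr / d if tr > 0 else 1.0)
        covs[i] = cov + ridge * np.eye(d)
        priors[i] = n
    if priors.sum() == 0:
        raise ValueError("no labelled frames")
    priors = priors / priors.sum()
    return GaussianClassModel(classes=classes, means=means, covariances=covs,
                              priors=priors, unseen=tuple(unseen))


def log_likelihood(model: GaussianClassModel, frame, class_label) -> float:
    """Gaussian log-density of a single frame under one class model."""
    return float(model.log_likelihood_vector(frame)[model.class_index[class_label]])


@dataclass
class LocationSensorModel:
    """Categorical observations of selected slots with per-slot confusion.

    Each observed symbol equals the true slot value with probability
    ``1 - epsilon`` and any of the ``m - 1`` other values with probability
    ``epsilon / (m - 1)``.  ``epsilon = 0`` is the noiseless indicator: any
    mismatch yields log-likelihood ``-inf`` (the state is eliminated).
    """

    domain: Domain
    slot_names: tuple
    epsilon: float = 0.0

    keyed_by = "state"

    def __post_init__(self):
        self.slot_names = tuple(self.slot_names)
        self._indices = []
        self._sizes = []
        for name in self.slot_names:
            if name not in self.domain.slot_index:
                raise KeyError(f"slot {name!r} not declared in domain")
            idx = self.domain.slot_index[name]
            self._indices.append(idx)
            self._sizes.append(len(self.domain.slots[idx].values))
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")

    def log_likelihood_state(self, obs: tuple, state: tuple) -> float:
        if len(obs) != len(self._indices):
            raise ValueError("observation arity does not match observed slots")
        total = 0.0
        for sym, idx, m in zip(obs, self._indices, self._sizes):
            truth = state[idx]
            if sym not in self.domain.slots[idx].values:
                raise ValueError(f"symbol {sym!r} outside domain of slot "
                                 f"{self.domain.slots[idx].name!r}")
            if sym == truth:
                p = 1.0 - self.epsilon
            else:
                p = self.epsilon / (m - 1) if m > 1 else 0.0
            if p <= 0.0:
                return -math.inf
            total += math.log(p)
        return total

    def observe(self, state: tuple, rng: np.random.Generator) -> tuple:
        """Draw one observation tuple from the confusion model."""
        out = []
        for idx, m in zip(self._indices, self._sizes):
            truth = state[idx]
            values = self.domain.slots[idx].values
            if m > 1 and rng.random() < self.epsilon:
                others = [v for v in values if v != truth]
                out.append(others[rng.integers(len(others))])
            else:
                out.append(truth)
        return tuple(out)


def generate_location_observations(model: LocationSensorModel, states: Sequence,
                                   seed: int | np.random.Generator = 0) -> list:
    """Per-frame location tuples drawn from the confusion model along a trace."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [model.observe(s, rng) for s in states]


def scramble(frames, labels, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Permute frames within each label class; the label sequence is unchanged.

    Frames carrying the same label are randomly exchanged among the
    positions of that label, which restores the i.i.d. property of
    class-conditional observations while preserving every label-conditional
    distribution exactly.
    """
    x = np.asarray(frames)
    labels = np.asarray(labels, dtype=object)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("frames and labels disagree in length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = x.copy()
    for c in sorted(set(labels)):
        pos = np.flatnonzero(labels == c)
        out[pos] = x[pos[rng.permutation(len(pos))]]
    return out


@dataclass
class ClassObservationSpec:
    """Generative per-class Gaussian spec for synthetic feature frames."""

    classes: tuple
    means: np.ndarray  # (C, d)
    sigma: float = 1.0
    drift: float = 0.0  # within-run deterministic bump magnitude

    def __post_init__(self):
        self.class_index = {c: i for i, c in enumerate(self.classes)}

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def to_gaussian_model(self) -> GaussianClassModel:
        """The exact generating model as a likelihood model (uniform priors)."""
        C, d = self.means.shape
        return GaussianClassModel(
            classes=self.classes,
            means=self.means.copy(),
            covariances=np.tile(self.sigma**2 * np.eye(d), (C, 1, 1)),
            priors=np.full(C, 1.0 / C),
        )


def make_class_spec(classes, dim: int = 6, separation: float = 3.0, sigma: float = 1.0,
                    drift: float = 0.0, seed: int = 12345) -> ClassObservationSpec:
    """Place class means at ``separation``-scaled random directions.

    The construction is seeded and deterministic; ``separation`` controls the
    frame-wise Bayes error of the resulting class-conditional Gaussians.
    """
    rng = np.random.default_rng(seed)
    classes = tuple(classes)
    dirs = rng.standard_normal((len(classes), dim))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return ClassObservationSpec(classes=classes, means=separation * dirs,
                                sigma=float(sigma), drift=float(drift))


def _runs(labels) -> list:
    """Maximal constant-label runs as (start, length) pairs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i - start))
            start = i
    return runs


def generate_observations(labels, spec: ClassObservationSpec,
                          seed: int | np.random.Generator = 0) -> np.ndarray:
    """Per-frame draws from the class Gaussians along a label sequence.

    With ``spec.drift > 0`` each run gets a random unit direction ``u`` and
    frame ``i`` at normalized run position ``p_i`` receives the deterministic
    offset ``drift * 4 (p_i - 1/2)^2 * u``: observations near run centers
    stay close to the class mean, while run edges drift away — the non-i.i.d.
    structure that scrambling is designed to destroy.
    """
    labels = list(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((len(labels), spec.dim))
    for start, length in _runs(labels):
        ci = spec.class_index[labels[start]]
        noise = rng.standard_normal((length, spec.dim)) * spec.sigma
        block = spec.means[ci] + noise
        if spec.drift > 0:
            u = rng.standard_normal(spec.dim)
            u /= np.linalg.norm(u)
            p = (np.arange(length) + 0.5) / length
            block = block + spec.drift * 4.0 * (p - 0.5)[:, None] ** 2 * u
        out[start : start + length] = block
    return out
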