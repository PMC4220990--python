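"""Per-action-class duration distributions with hazard-based termination.

Actions span several observation frames; the filter needs, at every frame,
the probability that the running action terminates within the next
inter-frame interval given that it has survived so far — the discrete-time
hazard

    h(e, dt) = P(T <= e + dt | T > e) = (F(e + dt) - F(e)) / (1 - F(e)).

Parametric families (lognormal, gamma, Weibull, exponential, positive-
truncated Cauchy) are evaluated in continuous time through scipy frozen
distributions and discretised only through the hazard; the empirical family
is a frame-grid multiset of observed durations.

Family choice is by maximum likelihood over a candidate list, with a
Kolmogorov-Smirnov statistic reported per candidate as a diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DurationModel",
    "DegenerateSamplesError",
    "fit",
    "select_family",
    "hazard",
    "PARAMETRIC_FAMILIES",
    "DEFAULT_CANDIDATES",
    "load_duration_bank",
    "save_duration_bank",
    "dumps_duration_bank",
    "loads_duration_bank",
]

PARAMETRIC_FAMILIES = ("lognormal", "gamma", "weibull", "exponential", "cauchy_pos")
DEFAULT_CANDIDATES = ("lognormal", "gamma", "weibull", "exponential", "cauchy_pos")


class DegenerateSamplesError(ValueError):
    """Samples carry no spread but the family requires one (e.g. lognormal)."""


def _cauchy_pos_logpdf(x, loc, scale):
    # Cauchy truncated to (0, inf) and renormalised.
    norm = stats.cauchy.sf(0.0, loc=loc, scale=scale)
    return stats.cauchy.logpdf(x, loc=loc, scale=scale) - math.log(norm)


def _cauchy_pos_cdf(x, loc, scale):
    x = np.asarray(x, dtype=float)
    c0 = stats.cauchy.cdf(0.0, loc=loc, scale=scale)
    out = (stats.cauchy.cdf(np.maximum(x, 0.0), loc=loc, scale=scale) - c0) / (1.0 - c0)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class DurationModel:
    """A fitted duration distribution for one action class.

    ``params`` by family:

    - lognormal: ``(mu, sigma)`` of log-duration
    - gamma: ``(shape, scale)``
    - weibull: ``(shape, scale)``
    - exponential: ``(rate,)``
    - cauchy_pos: ``(loc, scale)`` of the untruncated Cauchy
    - empirical: ``(durations, probabilities)`` as tuples
    """

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in PARAMETRIC_FAMILIES + ("empirical",):
            raise ValueError(f"unknown duration family {self.family!r}")
        if self.family == "empirical":
            values, probs = self.params
            if any(v <= 0 for v in values):
                raise ValueError("empirical durations must be positive")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("empirical probabilities must sum to 1")

    # -- distribution interface ------------------------------------------

    def _frozen(self):
        f, p = self.family, self.params
        if f == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if f == "gamma":
            return stats.gamma(a=p[0], scale=p[1])
        if f == "weibull":
            return stats.weibull_min(c=p[0], scale=p[1])
        if f == "exponential":
            return stats.expon(scale=1.0 / p[0])
        raise ValueError(f"no frozen form for family {self.family!r}")

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "empirical":
            values, probs = (np.asarray(a, dtype=float) for a in self.params)
            return np.where(
                t[..., None] >= values - 1e-12, probs, 0.0
            ).sum(axis=-1).clip(0.0, 1.0)
        if self.family == "cauchy_pos":
            return _cauchy_pos_cdf(t, *self.params)
        return self._frozen().cdf(np.maximum(t, 0.0))

    def sf(self, t):
        return 1.0 - self.cdf(t)

    def logpdf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "empirical":
            values, probs = (np.asarray(a, dtype=float) for a in self.params)
            mass = np.where(np.isclose(t[..., None], values), probs, 0.0).sum(axis=-1)
            with np.errstate(divide="ignore"):
                return np.log(mass)
        if self.family == "cauchy_pos":
            return _cauchy_pos_logpdf(t, *self.params)
        return self._frozen().logpdf(t)

    def pdf(self, t):
        return np.exp(self.logpdf(t))

    def log_likelihood(self, samples) -> float:
        return float(np.sum(self.logpdf(np.asarray(samples, dtype=float))))

    def mean(self) -> float:
        if self.family == "empirical":
            values, probs = (np.asarray(a, dtype=float) for a in self.params)
            return float(values @ probs)
        if self.family == "cauchy_pos":
            return math.nan  # heavy tails: undefined
        return float(self._frozen().mean())

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "empirical":
            values, probs = (np.asarray(a, dtype=float) for a in self.params)
            return rng.choice(values, size=size, p=probs)
        if self.family == "cauchy_pos":
            loc, scale = self.params
            # inverse-cdf sampling of the truncated Cauchy
            u = rng.random(size)
            c0 = stats.cauchy.cdf(0.0, loc=loc, scale=scale)
            return stats.cauchy.ppf(c0 + u * (1.0 - c0), loc=loc, scale=scale)
        return self._frozen().rvs(size=size, random_state=rng)


def fit(family: str, samples: Sequence[float]) -> DurationModel:
    """Maximum-likelihood fit of ``family`` to positive duration samples."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 duration samples")
    if np.any(x <= 0):
        raise ValueError("durations must be positive")
    spread = float(np.std(x)) > 0.0
    if family == "empirical":
        values, counts = np.unique(x, return_counts=True)
        probs = counts / counts.sum()
        return DurationModel("empirical", (tuple(values), tuple(probs)))
    if family == "exponential":
        return DurationModel("exponential", (1.0 / float(np.mean(x)),))
    if not spread:
        raise DegenerateSamplesError(
            f"family {family!r} requires sample spread; all durations are {x[0]}"
        )
    if family == "lognormal":
        logs = np.log(x)
        return DurationModel("lognormal", (float(np.mean(logs)), float(np.std(logs))))
    if family == "gamma":
        a, _, scale = stats.gamma.fit(x, floc=0.0)
        return DurationModel("gamma", (float(a), float(scale)))
    if family == "weibull":
        c, _, scale = stats.weibull_min.fit(x, floc=0.0)
        return DurationModel("weibull", (float(c), float(scale)))
    if family == "cauchy_pos":
        loc0, scale0 = float(np.median(x)), max(float(stats.iqr(x)) / 2.0, 1e-3)

        def nll(theta):
            loc, log_scale = theta
            scale = math.exp(log_scale)
            return -float(np.sum(_cauchy_pos_logpdf(x, loc, scale)))

        res = optimize.minimize(nll, [loc0, math.log(scale0)], method="Nelder-Mead")
        return DurationModel("cauchy_pos", (float(res.x[0]), float(math.exp(res.x[1]))))
    raise ValueError(f"unknown duration family {family!r}")


def select_family(samples, candidates=DEFAULT_CANDIDATES):
    """Fit every candidate family; return the maximum-likelihood model.

    Returns ``(model, report)`` where the report is a per-family table with
    log-likelihood, KS statistic and p-value (diagnostics only), parameters,
    and notes (fit failures, likelihood ties).  Ties go to the first
    candidate in list order and are flagged.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 samples for family selection")
    if not candidates:
        raise ValueError("empty candidate list")
    rows = []
    fitted = {}
    for fam in candidates:
        try:
            model = fit(fam, x)
        except (DegenerateSamplesError, ValueError) as exc:
            rows.append({"family": fam, "loglik": -math.inf, "ks_stat": math.nan,
                         "ks_p": math.nan, "params": None, "note": f"fit failed: {exc}"})
            continue
        ll = model.log_likelihood(x)
        if fam == "empirical":
            ks_stat, ks_p = math.nan, math.nan
        else:
            ks = stats.kstest(x, model.cdf)
            ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
        fitted[fam] = model
        rows.append({"family": fam, "loglik": ll, "ks_stat": ks_stat, "ks_p": ks_p,
                     "params": model.params, "note": ""})
    report = pd.DataFrame(rows)
    if not fitted:
        raise ValueError("no candidate family could be fitted")
    best_ll = report["loglik"].max()
    ties = report.index[np.isclose(report["loglik"], best_ll)].tolist()
    best_idx = ties[0]
    if len(ties) > 1:
        report.loc[ties, "note"] = (report.loc[ties, "note"] + " likelihood tie").str.strip()
    return fitted[report.loc[best_idx, "family"]], report


def hazard(model: DurationModel, elapsed, step) -> float | np.ndarray:
    """P(T <= elapsed + step | T > elapsed), clipped to [0, 1].

    When survival at ``elapsed`` is (numerically) zero the action must
    terminate: the hazard is 1.
    """
    elapsed = np.asarray(elapsed, dtype=float)
    if np.any(elapsed < 0):
        raise ValueError("elapsed must be >= 0")
    if np.any(np.asarray(step) <= 0):
        raise ValueError("step must be > 0")
    f1 = model.cdf(elapsed)
    f2 = model.cdf(elapsed + step)
    surv = 1.0 - f1
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(surv <= 1e-300, 1.0, (f2 - f1) / np.where(surv <= 1e-300, 1.0, surv))
    h = np.clip(h, 0.0, 1.0)
    return float(h) if h.ndim == 0 else h


# -- duration-bank file format -------------------------------------------------


def dumps_duration_bank(bank: dict) -> str:
    import yaml

    entries = []
    for cls in sorted(bank):
        m = bank[cls]
        if m.family == "empirical":
            values, probs = m.params
            entries.append({"class": cls, "family": "empirical",
                            "durations": [float(v) for v in values],
                            "probabilities": [float(p) for p in probs]})
        else:
            entries.append({"class": cls, "family": m.family,
                            "params": [float(p) for p in m.params]})
    return yaml.safe_dump({"durations": entries}, sort_keys=False)


def loads_duration_bank(text: str) -> dict:
    import yaml

    data = yaml.safe_load(text)
    bank = {}
    for entry in data["durations"]:
        fam = entry["family"]
        if fam == "empirical":
            bank[entry["class"]] = DurationModel(
                "empirical", (tuple(entry["durations"]), tuple(entry["probabilities"]))
            )
        else:
            bank[entry["class"]] = DurationModel(fam, tuple(entry["params"]))
    return bank


def save_duration_bank(bank: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_duration_bank(bank))


def load_duration_bank(path) -> dict:
    with open(path) as fh:
        return loads_duration_bank(fh.read())
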