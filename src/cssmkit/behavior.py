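"""Action-selection distributions and the generative trace simulator.

The agent's next action is drawn from a selection distribution over the
actions applicable in the current state.  The goal-directed *heuristic* kind
is a Boltzmann (log-linear) weighting of successor goal distances,

    p(a | s)  propto  exp(-lambda * h(apply(s, a))),

so that weight lambda = 0 is exactly uniform and large lambda approaches a
greedy shortest-path policy.  Successors with infinite goal distance
(livelocks) receive the capped value ``h_cap`` (one above the largest finite
distance by default) rather than probability zero, so a filter using the
heuristic can still track an agent that walks into a livelock.

The simulator alternates action selection and duration sampling to produce
ground-truth traces: per-frame class labels, ground actions, and LTS states.
Its default policy is an epsilon-uniform mixture over a *greedy* goal-
distance policy — deliberately a different family than the Boltzmann
inference heuristic, so simulated data does not hand the filter its own
behavior model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domain import Domain, GroundAction, applicable_actions, apply_action

__all__ = ["SelectionModel", "selection_distribution", "Trace", "simulate_trace"]


@dataclass
class SelectionModel:
    """A distribution over applicable actions, conditioned on the LTS state.

    kinds
    -----
    - ``uniform``: equal probability over applicable actions.
    - ``heuristic``: Boltzmann weighting ``exp(-weight * h(successor))`` of a
      goal-distance feature ``h`` (a mapping or callable on states).
    - ``epsilon_greedy``: with probability ``1 - epsilon`` uniform over the
      actions minimising ``h(successor)``, else uniform over all applicable
      actions (the simulator's default behavior policy).
    - ``tabular``: explicit per-state rows ``{state: {action_id: prob}}``.
    """

    kind: str
    feature: Mapping | Callable | None = None
    feature_name: str = "d"
    weight: float = 0.0
    h_cap: float | None = None
    epsilon: float = 0.1
    table: Mapping | None = None

    def __post_init__(self):
        if self.kind not in ("uniform", "heuristic", "epsilon_greedy", "tabular"):
            raise ValueError(f"unknown selection kind {self.kind!r}")
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ValueError("weight must be finite and >= 0")
        if self.kind in ("heuristic", "epsilon_greedy") and self.feature is None:
            raise ValueError(f"{self.kind} selection requires a goal-distance feature")
        if self.kind == "tabular" and self.table is None:
            raise ValueError("tabular selection requires a table")
        if self.kind == "heuristic" and self.h_cap is None and isinstance(self.feature, Mapping):
            finite = [v for v in self.feature.values() if math.isfinite(v)]
            self.h_cap = (max(finite) + 1.0) if finite else 1.0

    # convenience constructors -------------------------------------------

    @classmethod
    def uniform(cls):
        return cls(kind="uniform")

    @classmethod
    def heuristic(cls, feature, weight, feature_name="d", h_cap=None):
        return cls(kind="heuristic", feature=feature, weight=float(weight),
                   feature_name=feature_name, h_cap=h_cap)

    @classmethod
    def epsilon_greedy(cls, feature, epsilon=0.1, feature_name="d"):
        return cls(kind="epsilon_greedy", feature=feature, epsilon=float(epsilon),
                   feature_name=feature_name)

    @classmethod
    def tabular(cls, table):
        return cls(kind="tabular", table=table)

    def h(self, state) -> float:
        v = self.feature[state] if isinstance(self.feature, Mapping) else self.feature(state)
        return float(v)


def selection_distribution(domain: Domain, model: SelectionModel, state) -> dict:
    """Normalised ``{GroundAction: probability}`` over the applicable actions."""
    actions = applicable_actions(domain, state)
    if model.kind == "uniform":
        p = 1.0 / len(actions)
        return {a: p for a in actions}
    if model.kind == "tabular":
        row = model.table.get(state)
        if row is None:
            raise KeyError(f"tabular policy has no row for state {state!r}")
        probs = []
        for a in actions:
            if a.id not in row:
                raise KeyError(f"tabular row for {state!r} misses applicable action {a.id!r}")
            probs.append(float(row[a.id]))
        total = sum(probs)
        if total <= 0:
            raise ValueError(f"tabular row for {state!r} has zero total mass")
        return {a: p / total for a, p in zip(actions, probs)}
    hs = []
    for a in actions:
        h = model.h(apply_action(domain, state, a))
        if math.isinf(h):
            h = model.h_cap if model.h_cap is not None else max(
                [model.h(apply_action(domain, state, b)) for b in actions
                 if math.isfinite(model.h(apply_action(domain, state, b)))] or [0.0]
            ) + 1.0
        hs.append(h)
    if model.kind == "epsilon_greedy":
        hmin = min(hs)
        greedy = [i for i, h in enumerate(hs) if h == hmin]
        n, g = len(actions), len(greedy)
        probs = [model.epsilon / n + (1.0 - model.epsilon) / g * (i in set(greedy))
                 for i in range(n)]
        return {a: p for a, p in zip(actions, probs)}
    # Boltzmann: subtract the minimum before exponentiating for stability
    hmin = min(hs)
    ws = [math.exp(-model.weight * (h - hmin)) for h in hs]
    total = sum(ws)
    return {a: w / total for a, w in zip(actions, ws)}


@dataclass
class Segment:
    """One executed action: its span in frames and the state after its effects."""

    action_id: str
    class_label: str
    start_frame: int
    n_frames: int
    state: tuple


@dataclass
class Trace:
    """A simulated ground-truth execution at frame resolution."""

    domain: Domain
    frame_rate: float
    segments: list
    goal_reached: bool
    horizon_hit: bool

    @property
    def n_frames(self) -> int:
        return sum(s.n_frames for s in self.segments)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def frame_labels(self) -> np.ndarray:
        return np.array(
            [s.class_label for s in self.segments for _ in range(s.n_frames)], dtype=object
        )

    @property
    def frame_action_ids(self) -> np.ndarray:
        return np.array(
            [s.action_id for s in self.segments for _ in range(s.n_frames)], dtype=object
        )

    @property
    def frame_states(self) -> list:
        return [s.state for s in self.segments for _ in range(s.n_frames)]

    @property
    def action_sequence(self) -> list:
        return [s.action_id for s in self.segments]

    def durations_by_class(self) -> dict:
        """Observed action durations (seconds) grouped by class label."""
        out: dict = {}
        for s in self.segments:
            out.setdefault(s.class_label, []).append(s.n_frames / self.frame_rate)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "timestamp": self.timestamps,
                "class": self.frame_labels,
                "action": self.frame_action_ids,
                "state": [repr(s) for s in self.frame_states],
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_trace(
    domain: Domain,
    behavior: SelectionModel,
    durations: Mapping,
    frame_rate: float = 2.0,
    horizon: int = 2000,
    seed: int | np.random.Generator = 0,
) -> Trace:
    """Generate a ground-truth trace by alternating selection and duration draws.

    Effects are applied at action start, so every frame's state already
    reflects the running action.  The simulation stops when the goal is
    reached (a final wait segment is appended) or when ``horizon`` frames
    are exceeded (flagged, not fatal).
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = domain.initial
    segments: list[Segment] = []
    frames = 0
    goal_reached = domain.goal_satisfied(state)
    horizon_hit = False

    def draw_frames(class_label) -> int:
        d = float(durations[class_label].sample(rng))
        return max(1, int(round(d * frame_rate)))

    while not goal_reached:
        if frames >= horizon:
            horizon_hit = True
            break
        dist = selection_distribution(domain, behavior, state)
        actions = list(dist)
        probs = np.array([dist[a] for a in actions])
        action = actions[rng.choice(len(actions), p=probs)]
        state = apply_action(domain, state, action)
        n = min(draw_frames(action.class_label), horizon - frames)
        segments.append(Segment(action.id, action.class_label, frames, n, state))
        frames += n
        goal_reached = domain.goal_satisfied(state)
    if goal_reached and frames < horizon:
        wait = domain.wait_action
        n = min(draw_frames(wait.class_label), horizon - frames)
        segments.append(Segment(wait.id, wait.class_label, frames, n, state))
        frames += n
    return Trace(
        domain=domain,
        frame_rate=frame_rate,
        segments=segments,
        goal_reached=goal_reached,
        horizon_hit=horizon_hit,
    )
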