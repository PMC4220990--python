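"""Symbolic action-language domains compiled to labeled transition systems.

A :class:`Domain` declares typed objects, per-object slots (finite symbolic
value domains or bounded integers), and action schemata with conjunctive
preconditions and deterministic effects.  Grounding the schemata over the
object universe yields a finite set of :class:`GroundAction`; the induced
labeled transition system (LTS) is the triple of reachable states, ground
action labels, and the successor relation computed by :func:`apply_action`.

States are plain tuples of slot values in a canonical slot order (slots
sorted by name), which makes them hashable and cheap to compare — the basis
for state identification in the marginal filter.

Goal-directedness enters through shortest-path *goal distances* on the LTS
graph: the complete distance, a distance restricted to a subset of states
(e.g. the states visited by annotated executions), and a coarse script
heuristic that maps states to the number of remaining serial task steps.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "DomainError",
    "NotApplicableError",
    "SlotSpec",
    "ActionSchema",
    "GroundAction",
    "Domain",
    "StateGraph",
    "ground_actions",
    "applicable_actions",
    "apply_action",
    "reachable_states",
    "goal_distance_complete",
    "goal_distance_restricted",
    "script_distance",
    "detect_livelocks",
    "load_domain",
    "loads_domain",
    "save_domain",
    "dumps_domain",
    "WAIT_CLASS",
]

State = tuple
WAIT_CLASS = "WAIT"

_COND_RE = re.compile(r"^\s*(?P<slot>.+?)\s*(?P<op>==|<=|>=)\s*(?P<val>.+?)\s*$")
_EFF_RE = re.compile(r"^\s*(?P<slot>.+?)\s*(?P<op>:=|\+=|-=)\s*(?P<val>.+?)\s*$")


class DomainError(ValueError):
    """A domain definition is malformed (unknown slot, out-of-range effect, ...)."""


class NotApplicableError(RuntimeError):
    """An action was applied in a state where its preconditions do not hold."""


def _coerce(value):
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return int(value)
    s = str(value)
    try:
        return int(s)
    except ValueError:
        return s


@dataclass(frozen=True)
class SlotSpec:
    """A slot instance: a state variable with a finite ordered value domain."""

    name: str
    values: tuple
    is_int: bool = False

    def __post_init__(self):
        if not self.values:
            raise DomainError(f"slot {self.name!r} has an empty value domain")
        if self.is_int:
            lo, hi = min(self.values), max(self.values)
            if lo > hi:
                raise DomainError(f"slot {self.name!r}: integer range min > max")
            object.__setattr__(self, "values", tuple(range(lo, hi + 1)))

    @property
    def lo(self) -> int:
        return self.values[0]

    @property
    def hi(self) -> int:
        return self.values[-1]


@dataclass(frozen=True)
class ActionSchema:
    """A parameterised action template.

    ``preconditions`` are conjunctions of ``slot op value`` atoms with
    ``op`` one of ``==``, ``<=``, ``>=``; ``effects`` are ``slot := value``
    assignments or bounded integer ``+=``/``-=`` increments.  Slot names may
    contain parameter placeholders like ``loc(?x)``.
    """

    name: str
    params: tuple = ()  # ((param_name, type_name), ...)
    preconditions: tuple = ()  # ((slot_template, op, value), ...)
    effects: tuple = ()
    class_label: str = WAIT_CLASS
    is_wait: bool = False

    def __post_init__(self):
        if self.is_wait and self.effects:
            raise DomainError(f"wait schema {self.name!r} must have empty effects")

    @staticmethod
    def parse(name, params=(), pre=(), eff=(), class_label=WAIT_CLASS, is_wait=False):
        """Build a schema from string atoms like ``"loc(?x) == shelf"``."""
        pres = []
        for atom in pre:
            m = _COND_RE.match(atom)
            if not m:
                raise DomainError(f"schema {name!r}: cannot parse precondition {atom!r}")
            pres.append((m["slot"], m["op"], _coerce(m["val"])))
        effs = []
        for atom in eff:
            m = _EFF_RE.match(atom)
            if not m:
                raise DomainError(f"schema {name!r}: cannot parse effect {atom!r}")
            effs.append((m["slot"], m["op"], _coerce(m["val"])))
        return ActionSchema(
            name=name,
            params=tuple((str(p), str(t)) for p, t in params),
            preconditions=tuple(pres),
            effects=tuple(effs),
            class_label=class_label,
            is_wait=is_wait,
        )


@dataclass(frozen=True)
class GroundAction:
    """A schema instantiated with concrete object bindings.

    ``pre``/``eff`` carry resolved ``(slot_index, op, value)`` triples against
    the domain's canonical slot order, so applicability checks and successor
    computation are tuple lookups.
    """

    id: str
    schema_name: str
    class_label: str
    bindings: tuple  # ((param, object), ...)
    pre: tuple  # ((slot_idx, op, value), ...)
    eff: tuple  # ((slot_idx, op, value), ...)
    is_wait: bool = False

    def __repr__(self):  # pragma: no cover - debug aid
        return f"GroundAction({self.id})"


_WAIT_SCHEMA = ActionSchema(name="wait", class_label=WAIT_CLASS, is_wait=True)


class Domain:
    """A grounded action-language domain (the generator of the LTS).

    Parameters
    ----------
    objects:
        Mapping from type name to object names.
    slots:
        ``SlotSpec`` instances (slot instances, not templates).
    schemata:
        Action schemata.  A wait schema (always applicable, no effects) is
        appended automatically when none is declared.
    initial:
        Mapping slot name -> value, total over all slots.
    goal:
        Partial mapping slot name -> value (a conjunction of equality literals).
    script:
        Optional serial-task script: sequence of ``(condition mapping,
        remaining steps)`` pairs checked in order by :func:`script_distance`.
    """

    def __init__(self, objects, slots, schemata, initial, goal, script=None, name="domain"):
        self.name = name
        self.objects = {str(t): tuple(sorted(str(o) for o in objs)) for t, objs in objects.items()}
        self.slots = tuple(sorted(slots, key=lambda sp: sp.name))
        self.slot_index = {sp.name: i for i, sp in enumerate(self.slots)}
        if len(self.slot_index) != len(self.slots):
            raise DomainError("duplicate slot names")
        schemata = tuple(schemata)
        if not any(s.is_wait for s in schemata):
            schemata = schemata + (_WAIT_SCHEMA,)
        self.schemata = schemata
        self.initial = self._make_state(initial)
        self.goal = tuple(sorted((str(k), _coerce(v)) for k, v in goal.items()))
        for slot_name, value in self.goal:
            idx = self.slot_index.get(slot_name)
            if idx is None:
                raise DomainError(f"goal references undeclared slot {slot_name!r}")
            if value not in self.slots[idx].values:
                raise DomainError(f"goal value {value!r} not in domain of slot {slot_name!r}")
        self.script = None
        if script is not None:
            self.script = tuple(
                (self._compile_conds(when), int(remaining)) for when, remaining in script
            )
        self._ground: tuple | None = None
        self._raw_script = tuple((dict(w), int(r)) for w, r in script) if script else None

    # -- construction helpers ------------------------------------------------

    def _make_state(self, assignment: Mapping) -> State:
        values = [None] * len(self.slots)
        assignment = {str(k): _coerce(v) for k, v in assignment.items()}
        for slot_name, value in assignment.items():
            idx = self.slot_index.get(slot_name)
            if idx is None:
                raise DomainError(f"assignment references undeclared slot {slot_name!r}")
            if value not in self.slots[idx].values:
                raise DomainError(f"value {value!r} not in domain of slot {slot_name!r}")
            values[idx] = value
        missing = [sp.name for sp, v in zip(self.slots, values) if v is None]
        if missing:
            raise DomainError(f"assignment misses slots: {missing}")
        return tuple(values)

    def _compile_conds(self, when: Mapping) -> tuple:
        conds = []
        for slot_name, value in sorted((str(k), _coerce(v)) for k, v in when.items()):
            idx = self.slot_index.get(slot_name)
            if idx is None:
                raise DomainError(f"script references undeclared slot {slot_name!r}")
            conds.append((idx, "==", value))
        return tuple(conds)

    # -- convenience ---------------------------------------------------------

    def slot_value(self, state: State, slot_name: str):
        return state[self.slot_index[slot_name]]

    def state_dict(self, state: State) -> dict:
        return {sp.name: v for sp, v in zip(self.slots, state)}

    def goal_satisfied(self, state: State) -> bool:
        return all(state[self.slot_index[n]] == v for n, v in self.goal)

    def predicate(self, literals: Mapping):
        """Compile ``{slot: value}`` into a ``state -> bool`` predicate."""
        conds = self._compile_conds(literals)
        return lambda state: all(state[i] == v for i, _, v in conds)

    @property
    def ground(self) -> tuple:
        if self._ground is None:
            self._ground = ground_actions(self)
        return self._ground

    @property
    def actions_by_id(self) -> dict:
        if not hasattr(self, "_actions_by_id"):
            self._actions_by_id = {a.id: a for a in self.ground}
        return self._actions_by_id

    @property
    def wait_action(self) -> GroundAction:
        if not hasattr(self, "_wait"):
            self._wait = next(a for a in self.ground if a.is_wait)
        return self._wait

    @property
    def classes(self) -> tuple:
        """Sorted action-class alphabet of the grounded domain."""
        return tuple(sorted({a.class_label for a in self.ground}))


# -- grounding and successor computation -------------------------------------


def _resolve_slot(template: str, bindings: dict, domain: Domain, schema_name: str) -> int:
    name = template
    for p, obj in bindings.items():
        name = name.replace(f"?{p}", obj)
    idx = domain.slot_index.get(name)
    if idx is None:
        raise DomainError(f"schema {schema_name!r}: unknown slot {name!r} (from {template!r})")
    return idx


def ground_actions(domain: Domain) -> tuple:
    """Enumerate every type-respecting instantiation of every schema.

    The result is deterministic: sorted lexicographically by ground-action id.
    """
    out = []
    for schema in domain.schemata:
        pools = []
        for p, type_name in schema.params:
            objs = domain.objects.get(type_name)
            if objs is None:
                raise DomainError(
                    f"schema {schema.name!r}: parameter ?{p} has unbound type {type_name!r}"
                )
            pools.append(objs)
        for combo in itertools.product(*pools):
            bindings = {p: obj for (p, _), obj in zip(schema.params, combo)}
            gid = schema.name if not combo else f"{schema.name}({','.join(combo)})"
            pre = []
            for slot_t, op, value in schema.preconditions:
                idx = _resolve_slot(slot_t, bindings, domain, schema.name)
                sp = domain.slots[idx]
                if op in ("<=", ">=") and not sp.is_int:
                    raise DomainError(
                        f"schema {schema.name!r}: bound test on non-integer slot {sp.name!r}"
                    )
                if op == "==" and value not in sp.values:
                    raise DomainError(
                        f"schema {schema.name!r}: precondition value {value!r} "
                        f"not in domain of slot {sp.name!r}"
                    )
                pre.append((idx, op, value))
            eff = []
            touched = set()
            for slot_t, op, value in schema.effects:
                idx = _resolve_slot(slot_t, bindings, domain, schema.name)
                sp = domain.slots[idx]
                if op in ("+=", "-=") and not sp.is_int:
                    raise DomainError(
                        f"schema {schema.name!r}: increment on non-integer slot {sp.name!r}"
                    )
                if op == ":=" and value not in sp.values:
                    raise DomainError(
                        f"schema {schema.name!r}: effect value {value!r} "
                        f"not in domain of slot {sp.name!r}"
                    )
                if idx in touched:
                    raise DomainError(
                        f"schema {schema.name!r}: duplicate effect on slot {sp.name!r}"
                    )
                touched.add(idx)
                eff.append((idx, op, value))
            out.append(
                GroundAction(
                    id=gid,
                    schema_name=schema.name,
                    class_label=schema.class_label,
                    bindings=tuple(sorted(bindings.items())),
                    pre=tuple(pre),
                    eff=tuple(eff),
                    is_wait=schema.is_wait,
                )
            )
    out.sort(key=lambda a: a.id)
    ids = [a.id for a in out]
    if len(set(ids)) != len(ids):
        raise DomainError("ground-action ids are not unique")
    return tuple(out)


def _holds(state: State, pre: tuple) -> bool:
    for idx, op, value in pre:
        v = state[idx]
        if op == "==":
            if v != value:
                return False
        elif op == "<=":
            if not v <= value:
                return False
        elif op == ">=":
            if not v >= value:
                return False
        else:  # pragma: no cover - parser guarantees ops
            raise DomainError(f"unknown operator {op!r}")
    return True


def applicable_actions(domain: Domain, state: State) -> tuple:
    """All ground actions whose preconditions hold in ``state`` (wait included)."""
    return tuple(a for a in domain.ground if a.is_wait or _holds(state, a.pre))


def apply_action(domain: Domain, state: State, action: GroundAction) -> State:
    """Successor of ``state`` under ``action`` (deterministic, instantaneous).

    Applying the wait action is the identity.  Raises
    :class:`NotApplicableError` when preconditions fail and
    :class:`DomainError` when an integer effect leaves the declared range.
    """
    if action.is_wait:
        return state
    if not _holds(state, action.pre):
        raise NotApplicableError(f"action {action.id!r} is not applicable in {state!r}")
    values = list(state)
    for idx, op, value in action.eff:
        if op == ":=":
            values[idx] = value
        else:
            new = values[idx] + value if op == "+=" else values[idx] - value
            sp = domain.slots[idx]
            if not (sp.lo <= new <= sp.hi):
                raise DomainError(
                    f"action {action.id!r}: effect drives slot {sp.name!r} to {new}, "
                    f"outside [{sp.lo}, {sp.hi}]"
                )
            values[idx] = new
    return tuple(values)


# -- reachability and goal distances ------------------------------------------


@dataclass
class StateGraph:
    """BFS-explored LTS fragment with labeled edges and exploration metadata."""

    domain: Domain
    states: list  # BFS order
    index: dict  # state -> position in ``states``
    edges: list  # (src_idx, action_id, dst_idx), wait self-loops included
    depths: list  # BFS depth per state
    out_degree: list  # number of applicable non-wait actions per state
    truncated: bool
    _nx: nx.DiGraph | None = field(default=None, repr=False)

    @property
    def depth(self) -> int:
        return max(self.depths) if self.depths else 0

    def branching_summary(self) -> dict:
        import numpy as np

        d = np.asarray(self.out_degree, dtype=float)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3), "iqr": float(q3 - q1)}

    def to_networkx(self, include_wait: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for i, aid, j in self.edges:
            if not include_wait and i == j and self.domain.actions_by_id[aid].is_wait:
                continue
            g.add_edge(self.states[i], self.states[j])
        return g

    def goal_states(self, goal=None) -> list:
        if goal is None:
            sat = self.domain.goal_satisfied
        else:
            sat = self.domain.predicate(dict(goal))
        return [s for s in self.states if sat(s)]

    def save_edges(self, path) -> None:
        """Write a ``src<TAB>action<TAB>dst`` edge list (states by BFS index)."""
        with open(path, "w") as fh:
            fh.write("# src_idx\taction_id\tdst_idx\n")
            for i, aid, j in self.edges:
                fh.write(f"{i}\t{aid}\t{j}\n")


def reachable_states(domain: Domain, cap: int = 1_000_000) -> StateGraph:
    """Breadth-first exploration of the LTS from the initial state.

    Stops discovering new states once ``cap`` is reached; the result is then
    flagged ``truncated`` (edges between discovered states are still recorded).
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    init = domain.initial
    states = [init]
    index = {init: 0}
    depths = [0]
    out_degree = []
    edges = []
    truncated = False
    queue = deque([0])
    while queue:
        i = queue.popleft()
        s = states[i]
        deg = 0
        for a in applicable_actions(domain, s):
            t = apply_action(domain, s, a)
            if not a.is_wait:
                deg += 1
            j = index.get(t)
            if j is None:
                if len(states) >= cap:
                    truncated = True
                    continue
                j = len(states)
                index[t] = j
                states.append(t)
                depths.append(depths[i] + 1)
                queue.append(j)
            edges.append((i, a.id, j))
        out_degree.append(deg)
    return StateGraph(
        domain=domain,
        states=states,
        index=index,
        edges=edges,
        depths=depths,
        out_degree=out_degree,
        truncated=truncated,
    )


def _reverse_bfs_distances(graph: StateGraph, sources: Iterable[State], allowed=None) -> dict:
    g = nx.DiGraph()
    allowed_set = None if allowed is None else set(allowed)
    nodes = graph.states if allowed_set is None else [s for s in graph.states if s in allowed_set]
    g.add_nodes_from(nodes)
    for i, aid, j in graph.edges:
        if graph.domain.actions_by_id[aid].is_wait:
            continue  # wait self-loops never shorten a path; excluded from counting
        u, v = graph.states[i], graph.states[j]
        if allowed_set is not None and (u not in allowed_set or v not in allowed_set):
            continue
        g.add_edge(v, u)  # reversed
    sources = [s for s in sources if s in g]
    dist = {s: math.inf for s in graph.states}
    if sources:
        for s, d in nx.multi_source_dijkstra_path_length(g, sources, weight=None).items():
            dist[s] = float(d)
    return dist


def goal_distance_complete(graph: StateGraph, goal=None) -> dict:
    """Shortest non-wait action-path length from every state to a goal state.

    Livelocked states (no path to any goal state) map to ``math.inf``.
    """
    if graph.truncated:
        raise ValueError("goal distances require an untruncated state graph")
    return _reverse_bfs_distances(graph, graph.goal_states(goal))


def goal_distance_restricted(graph: StateGraph, goal=None, allowed: Iterable[State] = ()) -> dict:
    """Goal distances in the subgraph induced by ``allowed``; outside -> inf."""
    if graph.truncated:
        raise ValueError("goal distances require an untruncated state graph")
    allowed = set(allowed)
    goal_in = [s for s in graph.goal_states(goal) if s in allowed]
    if not goal_in:
        warnings.warn("no goal state inside the allowed set; all distances are infinite")
        return {s: math.inf for s in graph.states}
    return _reverse_bfs_distances(graph, goal_in, allowed=allowed)


def script_distance(domain: Domain, state: State, script=None) -> float:
    """Remaining serial task steps: value of the first matching script step."""
    script = domain.script if script is None else script
    if script is None:
        raise DomainError("domain declares no script")
    for conds, remaining in script:
        if all(state[i] == v for i, _, v in conds):
            return float(remaining)
    raise DomainError(f"no script step matches state {domain.state_dict(state)!r}")


def detect_livelocks(graph: StateGraph, goal=None) -> set:
    """Reachable states with infinite goal distance."""
    dist = goal_distance_complete(graph, goal)
    return {s for s, d in dist.items() if math.isinf(d)}


# -- file format ---------------------------------------------------------------


def _domain_to_dict(domain: Domain) -> dict:
    slots = []
    for sp in domain.slots:
        if sp.is_int:
            slots.append({"name": sp.name, "int": {"min": sp.lo, "max": sp.hi}})
        else:
            slots.append({"name": sp.name, "values": list(sp.values)})
    actions = []
    for s in domain.schemata:
        entry = {"name": s.name, "class": s.class_label}
        if s.params:
            entry["params"] = [[p, t] for p, t in s.params]
        if s.preconditions:
            entry["pre"] = [f"{sl} {op} {v}" for sl, op, v in s.preconditions]
        if s.effects:
            entry["eff"] = [f"{sl} {op} {v}" for sl, op, v in s.effects]
        if s.is_wait:
            entry["wait"] = True
        actions.append(entry)
    out = {
        "name": domain.name,
        "types": {t: list(objs) for t, objs in domain.objects.items()},
        "slots": slots,
        "actions": actions,
        "initial": domain.state_dict(domain.initial),
        "goal": {k: v for k, v in domain.goal},
    }
    if domain._raw_script is not None:
        out["script"] = [{"when": dict(w), "remaining": r} for w, r in domain._raw_script]
    return out


def _domain_from_dict(data: Mapping) -> Domain:
    types = {t: [str(o) for o in objs] for t, objs in (data.get("types") or {}).items()}
    slots = []
    for entry in data["slots"]:
        name = str(entry["name"])
        for_type = entry.get("for")
        names = [name] if for_type is None else [f"{name}({o})" for o in types[for_type]]
        for n in names:
            if "int" in entry:
                lo, hi = int(entry["int"]["min"]), int(entry["int"]["max"])
                slots.append(SlotSpec(n, tuple(range(lo, hi + 1)), is_int=True))
            else:
                slots.append(SlotSpec(n, tuple(_coerce(v) for v in entry["values"])))
    schemata = []
    for entry in data["actions"]:
        schemata.append(
            ActionSchema.parse(
                name=str(entry["name"]),
                params=[(p, t) for p, t in entry.get("params", [])],
                pre=entry.get("pre", []),
                eff=entry.get("eff", []),
                class_label=str(entry.get("class", WAIT_CLASS)),
                is_wait=bool(entry.get("wait", False)),
            )
        )
    script = None
    if "script" in data:
        script = [(e["when"], int(e["remaining"])) for e in data["script"]]
    return Domain(
        objects=types,
        slots=slots,
        schemata=schemata,
        initial=data["initial"],
        goal=data.get("goal", {}),
        script=script,
        name=str(data.get("name", "domain")),
    )


def dumps_domain(domain: Domain) -> str:
    return yaml.safe_dump(_domain_to_dict(domain), sort_keys=False)


def loads_domain(text: str) -> Domain:
    return _domain_from_dict(yaml.safe_load(text))


def save_domain(domain: Domain, path) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_domain(domain))


def load_domain(path) -> Domain:
    with open(path) as fh:
        return _domain_from_dict(yaml.safe_load(fh))
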