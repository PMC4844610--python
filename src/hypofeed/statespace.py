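"""Nondeterministic update semantics: the deduplicated state-transition tree.

Hypothalamic units update by *optional* rules: from any state, each
unit whose freshly computed net input differs from its stored one may
fire (or not), and every firing immediately triggers the *forced*
output-stage equations (NTSCA, NTSGLP1, VTA, NAc, FI).  Exploring all
firing orders from an initial state yields a tree whose nodes are
response configurations; the tree is deduplicated by a full-state key
at tolerance.  For the acyclic canonical wiring every branch ends in
the same terminal state (confluence), and the unique terminal reached
from the normal initial state defines the baseline responses.

Non-terminal states are the scientific payload: they model response
configurations in which some subtype has been prevented from updating
by neurons outside the modeled network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import (
    NET_TOLERANCE,
    ModelState,
    NetworkSpec,
    compute_net_input,
    propagate_output_stage,
    run_to_fixed_point,
    update_unit,
)

__all__ = [
    "StateKey",
    "ReachableSet",
    "state_key",
    "elaborate",
    "applicable_rules",
    "step",
    "enumerate_reachable",
    "terminal_and_baseline",
    "search",
    "parse_predicate",
    "StateSpaceError",
]

#: safety cap on the number of distinct enumerated states
MAX_STATES = 10 ** 6

StateKey = tuple


class StateSpaceError(RuntimeError):
    pass


def state_key(state: ModelState, spec: NetworkSpec, tol: float = NET_TOLERANCE) -> StateKey:
    """Canonical hashable key: per-element (net, response) rounded to tolerance,
    plus the substance/drug levels and override table (the static context)."""
    quant = lambda x: round(float(x) / tol)
    dyn = tuple((quant(state.net[e]), quant(state.resp[e])) for e in spec.elements)
    ctx = (
        tuple(quant(state.substances[s]) for s in spec.substances),
        tuple(quant(state.drugs[d]) for d in spec.drugs),
        tuple(sorted((k, quant(v)) for k, v in state.overrides.items())),
    )
    return dyn + ctx


def elaborate(state: ModelState, params, spec: NetworkSpec) -> ModelState:
    """Run all forced equations on a state (the elaborated root of the tree)."""
    return propagate_output_stage(state, params, spec)


def _fresh_nets(state: ModelState, params, spec: NetworkSpec, tol: float):
    """(unit, new_net) for every rule unit whose net input would change."""
    out = []
    for u in spec.rule_units:
        new = compute_net_input(u, state, params, spec)
        if abs(new - state.net[u]) > tol:
            out.append((u, new))
    return out


def applicable_rules(state: ModelState, params, spec: NetworkSpec, tol: float = NET_TOLERANCE):
    """Hypothalamic units whose update rule would change their net input."""
    return [u for u, _ in _fresh_nets(state, params, spec, tol)]


def step(state: ModelState, unit: str, params, spec: NetworkSpec, tol: float = NET_TOLERANCE) -> ModelState:
    """Fire one applicable rule, then the forced output-stage equations.

    Pure; raises ``StateSpaceError`` if the unit's rule is not applicable.
    """
    new = compute_net_input(unit, state, params, spec)
    if abs(new - state.net[unit]) <= tol:
        raise StateSpaceError(f"rule for {unit} is not applicable in this state")
    out = state.copy()
    update_unit(out, unit, params, spec, net=new)
    return propagate_output_stage(out, params, spec)


@dataclass
class ReachableSet:
    """Deduplicated enumeration of every state reachable by some rule order."""

    spec: NetworkSpec
    init_key: StateKey
    states: dict = field(default_factory=dict)  # key -> ModelState
    layer: dict = field(default_factory=dict)  # key -> first-reached BFS layer
    terminal: set = field(default_factory=set)
    transitions: dict = field(default_factory=dict)  # (key, unit) -> key

    def __len__(self):
        return len(self.states)

    @property
    def max_layer(self) -> int:
        """Deepest first-reached layer: the layer by which every branch of the
        (deduplicated) tree has reached previously seen states."""
        return max(self.layer.values())

    def terminal_states(self):
        return [self.states[k] for k in sorted(self.terminal)]

    def responses(self, key: StateKey) -> dict:
        return dict(self.states[key].resp)

    def max_response(self, element: str) -> float:
        return max(float(s.resp[element]) for s in self.states.values())

    def to_frame(self, keys=None):
        import pandas as pd

        keys = sorted(self.states) if keys is None else list(keys)
        rows = []
        for k in keys:
            s = self.states[k]
            row = {"layer": self.layer[k], "terminal": k in self.terminal}
            row.update({e: float(s.resp[e]) for e in self.spec.elements})
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_reachable(init: ModelState | None, params, spec: NetworkSpec,
                        tol: float = NET_TOLERANCE, max_states: int = MAX_STATES) -> ReachableSet:
    """Breadth-first enumeration of the full state-transition tree.

    ``init`` defaults to the normal initial state; it is elaborated
    (forced equations run) before becoming the layer-0 root.  Complete:
    every state reachable by some firing order appears exactly once,
    tagged with the first BFS layer at which it is reached.
    """
    from .network import make_initial_state

    root = elaborate(init if init is not None else make_initial_state(spec), params, spec)
    rkey = state_key(root, spec, tol)
    rs = ReachableSet(spec=spec, init_key=rkey)
    rs.states[rkey] = root
    rs.layer[rkey] = 0
    frontier = [rkey]
    depth = 0
    while frontier:
        depth += 1
        nxt = []
        for key in frontier:
            state = rs.states[key]
            fired = _fresh_nets(state, params, spec, tol)
            if not fired:
                rs.terminal.add(key)
                continue
            for unit, new in fired:
                succ = state.copy()
                update_unit(succ, unit, params, spec, net=new)
                succ = propagate_output_stage(succ, params, spec)
                skey = state_key(succ, spec, tol)
                rs.transitions[(key, unit)] = skey
                if skey not in rs.states:
                    if len(rs.states) >= max_states:
                        raise StateSpaceError(f"state cap {max_states} exceeded")
                    rs.states[skey] = succ
                    rs.layer[skey] = depth
                    nxt.append(skey)
        frontier = nxt
    return rs


def terminal_and_baseline(init: ModelState | None, params, spec: NetworkSpec,
                          tol: float = NET_TOLERANCE, require_confluence: bool = True):
    """Enumerate, return (reachable, terminal states, baseline configuration).

    Asserts confluence (a single terminal) and agreement with the
    imperative fixed-point run when ``require_confluence`` is set, as
    holds for any acyclic wiring.
    """
    from .network import make_initial_state

    if init is None:
        init = make_initial_state(spec)
    rs = enumerate_reachable(init, params, spec, tol)
    terminals = rs.terminal_states()
    if require_confluence:
        if len(terminals) != 1:
            raise StateSpaceError(f"confluence violation: {len(terminals)} terminal states")
        fixed = run_to_fixed_point(init, params, spec, tol)
        if state_key(fixed, spec, tol) != next(iter(rs.terminal)):
            raise StateSpaceError("enumeration terminal differs from imperative fixed point")
    baseline = terminals[0] if len(terminals) == 1 else None
    return rs, terminals, baseline


def search(reachable: ReachableSet, predicate, include_init: bool = False):
    """All deduplicated states satisfying ``predicate`` and their count.

    Mirrors the declarative engine's ``=>+`` search: states reached by
    at least one rule execution, so the elaborated initial state is
    excluded unless ``include_init`` is set (or it is re-reached later).
    ``predicate`` is a callable on a ModelState, e.g. from
    :func:`parse_predicate`.
    """
    init_rereached = reachable.init_key in set(reachable.transitions.values())
    keys = [
        k
        for k in sorted(reachable.states)
        if (include_init or k != reachable.init_key or init_rereached)
        and predicate(reachable.states[k])
    ]
    return keys, len(keys)


def parse_predicate(text: str, baseline: ModelState | None = None,
                    reachable: ReachableSet | None = None):
    """Build a conjunction predicate from a comma-separated mini-DSL.

    Atoms: ``UNIT==0``, ``UNIT>0``, ``UNIT>CONST``, ``UNIT>baseline``,
    ``UNIT>1.3*baseline``, ``UNIT>20%max``.  Thresholds referencing the
    baseline or the per-unit maximum require the corresponding argument.
    """
    atoms = []
    for raw in text.split(","):
        expr = raw.strip().replace(" ", "")
        if "==" in expr:
            unit, rhs = expr.split("==")
            op = "eq"
        elif ">" in expr:
            unit, rhs = expr.split(">")
            op = "gt"
        else:
            raise ValueError(f"cannot parse atom {raw!r}")
        if reachable is not None and unit not in reachable.spec.elements:
            raise ValueError(f"unknown unit {unit!r}")
        if rhs.endswith("%max"):
            if reachable is None:
                raise ValueError("percent-of-max threshold needs a reachable set")
            thr = float(rhs[:-4]) / 100.0 * reachable.max_response(unit)
        elif rhs.endswith("baseline"):
            if baseline is None:
                raise ValueError("baseline-relative threshold needs a baseline state")
            factor = rhs[: -len("baseline")].rstrip("*")
            thr = (float(factor) if factor else 1.0) * float(baseline.resp[unit])
        else:
            thr = float(rhs)
        atoms.append((unit, op, thr))

    def predicate(state: ModelState) -> bool:
        for unit, op, thr in atoms:
            v = float(state.resp[unit])
            if op == "eq" and v != thr:
                return False
            if op == "gt" and not v > thr:
                return False
        return True

    return predicate
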