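"""Tiny synthetic networks and a brute-force enumeration oracle.

These toys share the production update semantics but are small enough
(2-4 rule units) to enumerate by naive recursion over *all* firing
orders without deduplication.  They exercise the engine's semantics,
not the biology.
"""

from __future__ import annotations

import numpy as np

from .network import (
    Ligand,
    ModelState,
    NetworkSpec,
    ParameterVector,
    ReceptorSpec,
    UnitSpec,
    compute_net_input,
    make_initial_state,
    propagate_output_stage,
    update_unit,
)
from .statespace import StateSpaceError, elaborate, state_key

__all__ = ["make_toy_chain", "make_random_toy", "brute_force_enumerate"]


def make_toy_chain(n_units: int, weights=1.0, input_weight: float = 1.0,
                   biases=0.0) -> tuple[NetworkSpec, ParameterVector]:
    """Linear chain U1 -> U2 -> ... -> Un, all optional-rule units.

    U1 receives the single substance ``input`` with strength
    ``input_weight``; link k carries weight ``weights[k]`` (negative
    values make the link inhibitory).
    """
    if not 2 <= n_units <= 4:
        raise ValueError("toy chains have 2 to 4 units")
    weights = np.broadcast_to(np.asarray(weights, dtype=float), (n_units - 1,))
    biases = np.broadcast_to(np.asarray(biases, dtype=float), (n_units,))
    units = tuple(UnitSpec(f"U{i+1}", True) for i in range(n_units))
    receptors = [ReceptorSpec("U1", "IN", +1, (Ligand("substance", "input"),))]
    releases = {}
    for i in range(n_units - 1):
        src, tgt = f"U{i+1}", f"U{i+2}"
        releases[src] = {"T": (tgt,)}
        receptors.append(
            ReceptorSpec(tgt, "R", -1 if weights[i] < 0 else +1, (Ligand("unit", src, "T"),))
        )
    spec = NetworkSpec(
        name=f"toy_chain_{n_units}",
        units=units,
        receptors=tuple(receptors),
        releases=releases,
        output_stage_order=(),
        substances=("input",),
        drugs=(),
        fi_element=None,
    )
    values = np.concatenate([[input_weight], np.abs(weights), biases])
    return spec, ParameterVector(spec, values)


def make_random_toy(seed: int, n_units: int | None = None,
                    edge_prob: float = 0.5) -> tuple[NetworkSpec, ParameterVector]:
    """Seeded random acyclic toy: 2-4 rule units, random signed wiring.

    Weights are drawn uniformly in [0, 2] and biases in [-1, 1]; every
    unit senses the input substance with probability 1/2 (the first
    always does, so something fires).
    """
    rng = np.random.default_rng(seed)
    n = int(n_units if n_units is not None else rng.integers(2, 5))
    units = tuple(UnitSpec(f"U{i+1}", True) for i in range(n))
    receptors = []
    releases: dict = {}
    for i in range(n):
        uid = f"U{i+1}"
        if i == 0 or rng.random() < 0.5:
            receptors.append(ReceptorSpec(uid, "IN", +1, (Ligand("substance", "input"),)))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                src, tgt = f"U{i+1}", f"U{j+1}"
                releases.setdefault(src, {"T": ()})
                releases[src]["T"] = releases[src]["T"] + (tgt,)
                sign = -1 if rng.random() < 0.5 else +1
                receptors.append(ReceptorSpec(tgt, f"R{i+1}", sign, (Ligand("unit", src, "T"),)))
    spec = NetworkSpec(
        name=f"toy_random_{seed}",
        units=units,
        receptors=tuple(receptors),
        releases=releases,
        output_stage_order=(),
        substances=("input",),
        drugs=(),
        fi_element=None,
    )
    strengths = rng.uniform(0.0, 2.0, len(receptors))
    biases = rng.uniform(-1.0, 1.0, n)
    return spec, ParameterVector(spec, np.concatenate([strengths, biases]))


def brute_force_enumerate(spec: NetworkSpec, params, init: ModelState | None = None,
                          tol: float = 1e-9, max_visits: int = 200_000) -> dict:
    """Reference answer for ``enumerate_reachable``: exhaustive recursion
    over all rule firing orders, collapsed to a set afterwards.

    Returns ``{key: state}`` over every state visited along any firing
    order (including the elaborated initial state).  Guarded against
    explosion; intended for networks with at most 4 rule units.
    """
    if len(spec.rule_units) > 4:
        raise ValueError("brute-force oracle is limited to 4 rule units")
    root = elaborate(init if init is not None else make_initial_state(spec), params, spec)
    seen: dict = {}
    visits = 0

    def recurse(state: ModelState):
        nonlocal visits
        visits += 1
        if visits > max_visits:
            raise StateSpaceError("brute-force explosion guard tripped")
        seen.setdefault(state_key(state, spec, tol), state)
        for u in spec.rule_units:
            new = compute_net_input(u, state, params, spec)
            if abs(new - state.net[u]) > tol:
                succ = state.copy()
                update_unit(succ, u, params, spec, net=new)
                succ = propagate_output_stage(succ, params, spec)
                recurse(succ)

    recurse(root)
    return seen
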