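"""Network data model and deterministic update computations.

The food-intake control circuit is a feedforward network of 12 neural
units (8 hypothalamic: AgRP, POMC, NGABA, OXT, MCH, OX, LHGal, NT; and
4 output-stage: NTSCA, NTSGLP1, VTA, NAc) plus a food-intake (FI)
element.  Each unit represents one anatomically and neurochemically
defined neural subtype.  A unit's net input is the sum over its
receptors of ``sign * strength * (summed cognate ligand levels)`` plus
an intrinsic bias; its response is the net input bounded at zero
(firing rates cannot be negative), gated by a live flag (0 after a
lesion) and shifted by any opto/chemogenetic somatic stimulation:

    response = live * max(0, net + stim)

Transmitter release equals the releasing unit's response.  Three
receptor-level modulations are supported:

* ``risperidone_halving`` -- the effective 5HT2C receptor strength is
  ``max(0, strength - risperidone/2)``;
* ``melanocortin_inverse_agonism`` -- AgRP peptide is subtracted from
  the melanocortin ligand sum before weighting (AgRP is an inverse
  agonist of MC3R/MC4R);
* ``ntsca_cck_gate`` -- the CCK term enters NTSCA's net input only when
  the leptin/ghrelin/OX/OXT modulator sum is positive and both CCK and
  the CCK receptor strength are positive (OXT and leptin sensitize,
  ghrelin and OX desensitize, NTSCA to peripheral CCK).

All arithmetic here is written so that levels and parameters may be
plain floats (one model instance) or equal-shaped numpy arrays (a whole
GA population evaluated at once).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Ligand",
    "ReceptorSpec",
    "UnitSpec",
    "NetworkSpec",
    "ParameterVector",
    "ModelState",
    "canonical_network",
    "make_initial_state",
    "compute_net_input",
    "gated_net_input_ntsca",
    "unit_response",
    "update_unit",
    "propagate_output_stage",
    "run_to_fixed_point",
    "ConvergenceError",
]

#: tolerance below which a net-input change does not count as a change
NET_TOLERANCE = 1e-9

#: sweep bound: an acyclic 12-unit network must settle within this many sweeps
MAX_SWEEPS = 13

HOOKS = ("none", "risperidone_halving", "melanocortin_inverse_agonism", "ntsca_cck_gate")


class ConvergenceError(RuntimeError):
    """Raised when a fixed-point run does not settle within the sweep bound.

    For an acyclic wiring this cannot happen; seeing it means the
    network specification contains a cycle.
    """


def _pos(x):
    """max(0, x) for floats or arrays."""
    if isinstance(x, np.ndarray):
        return np.maximum(0.0, x)
    return x if x > 0.0 else 0.0


def _where(cond, a, b):
    if isinstance(cond, np.ndarray):
        return np.where(cond, a, b)
    return a if cond else b


# ---------------------------------------------------------------------------
# declarative wiring types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ligand:
    """One source feeding a receptor.

    ``kind`` is ``"substance"`` (endogenous hormone/nutrient),
    ``"drug"`` (exogenous), or ``"unit"`` (a transmitter released by
    another unit, in which case ``transmitter`` names it).
    """

    kind: str
    name: str
    transmitter: str | None = None

    def to_json(self):
        d = {"kind": self.kind, "name": self.name}
        if self.transmitter is not None:
            d["transmitter"] = self.transmitter
        return d

    @classmethod
    def from_json(cls, d):
        return cls(d["kind"], d["name"], d.get("transmitter"))


@dataclass(frozen=True)
class ReceptorSpec:
    """A receptor expressed by ``unit``: signed, weighted ligand summation."""

    unit: str
    name: str
    sign: int  # +1 excitatory, -1 inhibitory
    ligands: tuple[Ligand, ...]
    hook: str = "none"
    inverse_agonists: tuple[Ligand, ...] = ()

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError(f"receptor sign must be +/-1, got {self.sign}")
        if self.hook not in HOOKS:
            raise ValueError(f"unknown modulation hook {self.hook!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.unit, self.name)


@dataclass(frozen=True)
class UnitSpec:
    id: str
    hypothalamic: bool


@dataclass
class NetworkSpec:
    """Declarative wiring: units, receptors, transmitter routing.

    ``units`` excludes the FI element, which is named by ``fi_element``
    and always updated last in the output stage.  Hypothalamic units
    update by optional rules (they generate state-transition branches);
    all other elements update by forced equations immediately after any
    rule fires.
    """

    name: str
    units: tuple[UnitSpec, ...]
    receptors: tuple[ReceptorSpec, ...]
    releases: dict  # unit -> {transmitter -> tuple(target elements)}
    output_stage_order: tuple[str, ...]
    substances: tuple[str, ...]
    drugs: tuple[str, ...]
    fi_element: str | None = "FI"

    # --- derived indexes -------------------------------------------------
    def __post_init__(self):
        self.unit_ids = tuple(u.id for u in self.units)
        self.rule_units = tuple(u.id for u in self.units if u.hypothalamic)
        self.elements = self.unit_ids + ((self.fi_element,) if self.fi_element else ())
        by_unit: dict[str, list[ReceptorSpec]] = {e: [] for e in self.elements}
        for rec in self.receptors:
            if rec.unit not in by_unit:
                raise ValueError(f"receptor on undeclared element {rec.unit!r}")
            by_unit[rec.unit].append(rec)
        self.receptors_by_unit = {u: tuple(v) for u, v in by_unit.items()}
        # optimizable parameters: every receptor strength, then every bias
        names = [f"{r.unit}.{r.name}" for r in self.receptors]
        names += [f"{e}.bias" for e in self.elements]
        self.param_names = tuple(names)
        self.param_index = {n: i for i, n in enumerate(names)}
        self._rec_index = {r.key: self.param_index[f"{r.unit}.{r.name}"] for r in self.receptors}
        self._bias_index = {e: self.param_index[f"{e}.bias"] for e in self.elements}
        self.validate()

    # --- queries ----------------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def receptor(self, unit: str, name: str) -> ReceptorSpec:
        for r in self.receptors_by_unit[unit]:
            if r.name == name:
                return r
        raise KeyError(f"{unit} has no receptor {name}")

    def strength_index(self, unit: str, name: str) -> int:
        return self._rec_index[(unit, name)]

    def bias_index(self, element: str) -> int:
        return self._bias_index[element]

    def ligand_flow_edges(self) -> list[tuple[str, str]]:
        """Directed unit->element edges implied by the release map."""
        edges = []
        for src, routes in self.releases.items():
            for targets in routes.values():
                edges.extend((src, t) for t in targets)
        return edges

    # --- validation -------------------------------------------------------
    def validate(self) -> None:
        ids = set(self.elements)
        if len(ids) != len(self.elements):
            raise ValueError("duplicate element ids")
        for rec in self.receptors:
            for lig in rec.ligands + rec.inverse_agonists:
                if lig.kind == "substance" and lig.name not in self.substances:
                    raise ValueError(f"undeclared substance {lig.name!r}")
                elif lig.kind == "drug" and lig.name not in self.drugs:
                    raise ValueError(f"undeclared drug {lig.name!r}")
                elif lig.kind == "unit":
                    routes = self.releases.get(lig.name, {})
                    if rec.unit not in routes.get(lig.transmitter, ()):
                        raise ValueError(
                            f"{lig.name} does not release {lig.transmitter} onto {rec.unit}"
                        )
        for u in self.output_stage_order:
            if u not in ids:
                raise ValueError(f"output stage names unknown element {u!r}")
        if self.fi_element and self.output_stage_order and self.output_stage_order[-1] != self.fi_element:
            raise ValueError("output stage must end with the FI element")
        # feedforward check: ligand-flow graph over elements is acyclic
        edges = self.ligand_flow_edges()
        order = _topological_order(self.elements, edges)
        if order is None:
            raise ValueError("ligand-flow graph is not acyclic")
        self._topo_order = tuple(u for u in order if u in self.rule_units)

    def validate_canonical(self, n_params: int = 51) -> None:
        """Structural checksum for the canonical food-intake wiring."""
        hyp = [u.id for u in self.units if u.hypothalamic]
        out = [u.id for u in self.units if not u.hypothalamic]
        if len(self.units) != 12 or len(hyp) != 8 or len(out) != 4:
            raise ValueError("canonical spec requires 12 units (8 hypothalamic + 4 output-stage)")
        if len(self.substances) != 5:
            raise ValueError("canonical spec requires 5 endogenous substances")
        if self.n_params != n_params:
            raise ValueError(f"parameter checksum {self.n_params} != {n_params}")

    # --- serialization ----------------------------------------------------
    def to_json(self) -> dict:
        return {
            "name": self.name,
            "substances": list(self.substances),
            "drugs": list(self.drugs),
            "units": [{"id": u.id, "hypothalamic": u.hypothalamic} for u in self.units],
            "receptors": [
                {
                    "unit": r.unit,
                    "name": r.name,
                    "sign": r.sign,
                    "ligands": [l.to_json() for l in r.ligands],
                    "hook": r.hook,
                    "inverse_agonists": [l.to_json() for l in r.inverse_agonists],
                }
                for r in self.receptors
            ],
            "releases": {u: {t: list(tg) for t, tg in routes.items()} for u, routes in self.releases.items()},
            "output_stage_order": list(self.output_stage_order),
            "fi_element": self.fi_element,
        }

    @classmethod
    def from_json(cls, d: dict) -> "NetworkSpec":
        return cls(
            name=d["name"],
            units=tuple(UnitSpec(u["id"], u["hypothalamic"]) for u in d["units"]),
            receptors=tuple(
                ReceptorSpec(
                    r["unit"],
                    r["name"],
                    r["sign"],
                    tuple(Ligand.from_json(l) for l in r["ligands"]),
                    r.get("hook", "none"),
                    tuple(Ligand.from_json(l) for l in r.get("inverse_agonists", [])),
                )
                for r in d["receptors"]
            ),
            releases={u: {t: tuple(tg) for t, tg in routes.items()} for u, routes in d["releases"].items()},
            output_stage_order=tuple(d["output_stage_order"]),
            substances=tuple(d["substances"]),
            drugs=tuple(d["drugs"]),
            fi_element=d.get("fi_element"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _topological_order(nodes: Sequence[str], edges: Iterable[tuple[str, str]]):
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    indeg = {n: 0 for n in nodes}
    for a, b in edges:
        succ[a].append(b)
        indeg[b] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    order = []
    while queue:
        n = queue.pop(0)
        order.append(n)
        for m in succ[n]:
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    return order if len(order) == len(nodes) else None


def canonical_network() -> NetworkSpec:
    """Load the canonical 12-unit food-intake control wiring (51 parameters)."""
    with resources.files("hypofeed.data").joinpath("canonical_network.json").open() as fh:
        spec = NetworkSpec.from_json(json.load(fh))
    spec.validate_canonical()
    return spec


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


class ParameterVector:
    """Named receptor strengths and unit biases (51 for the canonical spec).

    Receptor strengths are nonnegative; excitation/inhibition lives in
    the wiring signs, not in the parameter values.  Biases may take any
    sign.
    """

    def __init__(self, spec: NetworkSpec, values):
        if isinstance(values, Mapping):
            missing = set(spec.param_names) - set(values)
            extra = set(values) - set(spec.param_names)
            if missing or extra:
                raise ValueError(f"parameter keys do not match spec (missing={sorted(missing)}, extra={sorted(extra)})")
            values = np.array([float(values[n]) for n in spec.param_names])
        else:
            values = np.asarray(values, dtype=float)
            if values.shape[0] != spec.n_params:
                raise ValueError(f"expected {spec.n_params} parameters, got {values.shape[0]}")
        n_strengths = len(spec.receptors)
        if np.any(values[:n_strengths] < 0):
            raise ValueError("receptor strengths must be nonnegative")
        self.spec = spec
        self.values = values

    def __len__(self):
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.spec.param_index[name]])

    @property
    def strengths(self) -> dict:
        return {r.key: float(self.values[self.spec.strength_index(*r.key)]) for r in self.spec.receptors}

    @property
    def biases(self) -> dict:
        return {e: float(self.values[self.spec.bias_index(e)]) for e in self.spec.elements}

    def distance(self) -> float:
        """Euclidean distance from the zero vector (the archive ordering key)."""
        return float(np.linalg.norm(self.values))

    def to_dict(self) -> dict:
        return {n: float(v) for n, v in zip(self.spec.param_names, self.values)}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path, spec: NetworkSpec) -> "ParameterVector":
        with open(path) as fh:
            return cls(spec, json.load(fh))

    @classmethod
    def zeros(cls, spec: NetworkSpec) -> "ParameterVector":
        return cls(spec, np.zeros(spec.n_params))


def _param_array(params) -> np.ndarray:
    """Accept a ParameterVector or a raw (n_params,) / (n_params, pop) array."""
    return params.values if isinstance(params, ParameterVector) else np.asarray(params, dtype=float)


# ---------------------------------------------------------------------------
# model state
# ---------------------------------------------------------------------------


@dataclass
class ModelState:
    """One node of the transition system.

    ``net``/``resp`` carry each element's stored net input and response
    (FI included).  ``live`` is 1 for intact units, 0 after a lesion or
    chemogenetic silencing.  ``stim`` is an additive somatic drive.
    ``overrides`` maps (source, target) pairs to a forced delivered
    transmitter level (projection photo-stimulation or blockade).
    """

    substances: dict
    drugs: dict
    net: dict
    resp: dict
    live: dict
    stim: dict
    overrides: dict

    def copy(self) -> "ModelState":
        return ModelState(
            dict(self.substances),
            dict(self.drugs),
            dict(self.net),
            dict(self.resp),
            dict(self.live),
            dict(self.stim),
            dict(self.overrides),
        )

    @property
    def fi(self):
        return self.resp.get("FI", 0.0)


def make_initial_state(spec: NetworkSpec, substance_levels=None, drug_levels=None) -> ModelState:
    """Not-yet-updated initial state: all nets/responses 0, everything alive.

    Default levels are 1.0 for every endogenous substance (the "normal"
    input producing a medium baseline food intake) and 0.0 for every
    drug.
    """
    substances = {s: 1.0 for s in spec.substances}
    if substance_levels:
        unknown = set(substance_levels) - set(spec.substances)
        if unknown:
            raise ValueError(f"unknown substances {sorted(unknown)}")
        substances.update(substance_levels)
    drugs = {d: 0.0 for d in spec.drugs}
    if drug_levels:
        unknown = set(drug_levels) - set(spec.drugs)
        if unknown:
            raise ValueError(f"unknown drugs {sorted(unknown)}")
        drugs.update(drug_levels)
    for name, level in list(substances.items()) + list(drugs.items()):
        if np.any(np.asarray(level) < 0):
            raise ValueError(f"negative level for {name}")
    zero = 0.0
    return ModelState(
        substances=substances,
        drugs=drugs,
        net={e: zero for e in spec.elements},
        resp={e: zero for e in spec.elements},
        live={e: 1 for e in spec.elements},
        stim={e: zero for e in spec.elements},
        overrides={},
    )


def _delivered(state: ModelState, src: str, transmitter: str, target: str):
    """Transmitter level delivered from src to target (override-aware)."""
    forced = state.overrides.get((src, target))
    if forced is not None:
        return forced
    return state.resp[src]


def _ligand_level(state: ModelState, lig: Ligand, target: str):
    if lig.kind == "substance":
        return state.substances[lig.name]
    if lig.kind == "drug":
        return state.drugs[lig.name]
    return _delivered(state, lig.name, lig.transmitter, target)


def compute_net_input(unit: str, state: ModelState, params, spec: NetworkSpec):
    """Net input: signed, strength-weighted per-receptor ligand sums plus bias.

    Ligands converging on one receptor are summed *before* weighting
    (e.g. GABA from AgRP and NGABA onto POMC's GABAR).  Hooks apply the
    risperidone halving, melanocortin inverse agonism, and NTSCA CCK
    gating described in the module docstring.
    """
    if unit not in spec.receptors_by_unit:
        raise KeyError(f"unknown element {unit!r}")
    P = _param_array(params)
    total = 0.0
    gate_term = None
    gate_strength = None
    gate_lig = None
    for rec in spec.receptors_by_unit[unit]:
        lig = 0.0
        for l in rec.ligands:
            lig = lig + _ligand_level(state, l, unit)
        for l in rec.inverse_agonists:
            lig = lig - _ligand_level(state, l, unit)
        strength = P[spec.strength_index(rec.unit, rec.name)]
        if rec.hook == "risperidone_halving":
            strength = _pos(strength - 0.5 * state.drugs["risperidone"])
        if rec.hook == "ntsca_cck_gate":
            gate_term = rec.sign * strength * lig
            gate_strength, gate_lig = strength, lig
            continue
        total = total + rec.sign * strength * lig
    if gate_term is not None:
        gate = (total > 0) & (gate_lig > 0) & (gate_strength > 0)
        total = total + _where(gate, gate_term, 0.0)
    return total + P[spec.bias_index(unit)]


def gated_net_input_ntsca(state: ModelState, params, spec: NetworkSpec):
    """NTSCA's CCK-sensitization-gated net input (thin alias).

    The leptin(+)/ghrelin(-)/OX(-)/OXT(+) modulator sum admits the
    CCKR*CCK term only when it is positive and both CCK and CCKR are
    positive; the bias is added in either case.
    """
    return compute_net_input("NTSCA", state, params, spec)


def unit_response(net, live, stim):
    """Response = live * max(0, net + stim); a lesioned unit is silent."""
    return live * _pos(net + stim)


def update_unit(state: ModelState, unit: str, params, spec: NetworkSpec, net=None) -> None:
    """Recompute one element's net and response in place."""
    if net is None:
        net = compute_net_input(unit, state, params, spec)
    state.net[unit] = net
    state.resp[unit] = unit_response(net, state.live[unit], state.stim[unit])


def propagate_output_stage(state: ModelState, params, spec: NetworkSpec) -> ModelState:
    """Forced-equation pass: update NTSCA, NTSGLP1, VTA, NAc, then FI, once each.

    The output stage is feedforward in this fixed topological order, so
    one pass reaches its fixed point; a second application changes
    nothing.  Returns a new state (the input is untouched).
    """
    out = state.copy()
    for u in spec.output_stage_order:
        update_unit(out, u, params, spec)
    return out


def _max_abs(x):
    if isinstance(x, np.ndarray):
        return float(np.max(np.abs(x))) if x.size else 0.0
    return abs(x)


def run_to_fixed_point(initial: ModelState, params, spec: NetworkSpec, tol: float = NET_TOLERANCE) -> ModelState:
    """Imperative semantics: sweep all units until no net input changes.

    Equivalent to the declarative enumeration's unique terminal state
    for acyclic wirings (confluence).  Raises :class:`ConvergenceError`
    if the sweep bound is exceeded, which signals a cyclic wiring.
    """
    state = initial.copy()
    order = spec._topo_order  # rule units in dependency order: fast, result-identical
    for _ in range(MAX_SWEEPS):
        changed = 0.0
        for u in order:
            new = compute_net_input(u, state, params, spec)
            delta = _max_abs(new - state.net[u])
            if delta > tol:
                changed = max(changed, delta)
            update_unit(state, u, params, spec, net=new)
        state = propagate_output_stage(state, params, spec)
        if changed <= tol:
            return state
    raise ConvergenceError(f"no fixed point within {MAX_SWEEPS} sweeps; wiring may be cyclic")
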