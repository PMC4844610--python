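""""Whenever p then q" invariant checking over the reachable state set.

An invariant ``context /\\ antecedent => consequent`` holds iff every
enumerated state satisfying the context and antecedent also satisfies
the consequent.  A false invariant carries a counterexample witness
(the lexicographically smallest violating state key, for reproducible
reports).  The proposition vocabulary matches the analyses of the
feeding-circuit paradoxes:

* ``eq0`` / ``gt0``              -- unit inactive / active at any level
* ``gt_baseline``                -- above the unit's baseline response
* ``high``                       -- more than 30% above baseline
* ``gt_pct_max(k)``              -- above k% of the unit's maximum
                                    response over the reachable set
* ``fully_active``               -- the unit has updated to its
                                    equation-determined value and it is
                                    positive
* ``fi_low`` / ``fi_medium`` / ``fi_high`` -- food intake in the
  low (<=43%), medium, or high (>=81%) band of its percent-of-maximum
  range
* ``nc``                         -- no condition (always true)

Thresholds are resolved against the parameterization's baseline and
per-unit maxima before evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ModelState, compute_net_input, unit_response
from .report import FI_HIGH, FI_LOW
from .statespace import ReachableSet

__all__ = [
    "Proposition",
    "InvariantResult",
    "check_invariant",
    "run_agrp_pomc_suite",
    "run_lh_gaba_suite",
    "AGRP_POMC_EXPECTED",
    "LH_GABA_EXPECTED",
]

_OPS = ("nc", "eq0", "gt0", "gt_baseline", "high", "gt_pct_max", "fully_active",
        "fi_low", "fi_medium", "fi_high")


@dataclass(frozen=True)
class Proposition:
    """One atomic condition on a unit's response (or on the FI class)."""

    unit: str
    op: str
    value: float | None = None  # percent for gt_pct_max

    def __post_init__(self):
        if self.op not in _OPS:
            raise ValueError(f"unknown proposition op {self.op!r}")
        if self.op == "gt_pct_max" and self.value is None:
            raise ValueError("gt_pct_max needs a percent value")

    def __str__(self):
        if self.op == "gt_pct_max":
            return f"{self.unit} > {self.value:g}% of max"
        return {"nc": f"{self.unit} = NC", "eq0": f"{self.unit} = 0",
                "gt0": f"{self.unit} > 0", "gt_baseline": f"{self.unit} > baseline",
                "high": f"{self.unit} = high", "fully_active": f"{self.unit} fully active",
                "fi_low": "FI = low", "fi_medium": "FI = medium",
                "fi_high": "FI = high"}[self.op]



class _Resolver:
    """Evaluates propositions against one enumerated reachable set."""

    def __init__(self, reachable: ReachableSet, baseline: ModelState, params):
        self.reachable = reachable
        self.baseline = baseline
        self.params = params
        self.spec = reachable.spec
        self.max = {e: reachable.max_response(e) for e in self.spec.elements}

    def holds(self, prop: Proposition, state: ModelState) -> bool:
        if prop.op == "nc":
            return True
        spec = self.spec
        v = float(state.resp[prop.unit])
        if prop.op == "eq0":
            return v == 0.0
        if prop.op == "gt0":
            return v > 0.0
        if prop.op == "gt_baseline":
            return v > float(self.baseline.resp[prop.unit])
        if prop.op == "high":
            return v > 1.3 * float(self.baseline.resp[prop.unit])
        if prop.op == "gt_pct_max":
            mx = self.max[prop.unit]
            if mx <= 0:
                raise ValueError(f"cannot resolve %-of-max threshold: max({prop.unit}) = 0")
            return v > (prop.value / 100.0) * mx
        if prop.op == "fully_active":
            net = compute_net_input(prop.unit, state, self.params, spec)
            settled = unit_response(net, state.live[prop.unit], state.stim[prop.unit])
            return v > 0.0 and abs(float(settled) - v) <= 1e-9
        # FI classes on percent-of-max food intake
        fi = spec.fi_element
        mx = self.max[fi]
        if mx <= 0:
            raise ValueError("cannot classify FI: maximum food intake is 0")
        pct = 100.0 * float(state.resp[fi]) / mx
        if prop.op == "fi_low":
            return pct <= FI_LOW
        if prop.op == "fi_high":
            return pct >= FI_HIGH
        return FI_LOW < pct < FI_HIGH


@dataclass
class InvariantResult:
    holds: bool
    vacuous: bool
    n_checked: int
    witness_key: tuple | None
    witness: ModelState | None

    def __bool__(self):
        return self.holds


def check_invariant(reachable: ReachableSet, baseline: ModelState, params,
                    context, antecedent, consequent: Proposition,
                    include_init: bool = True) -> InvariantResult:
    """True iff the consequent holds in every reachable state satisfying
    context and antecedent.

    An unsatisfiable context/antecedent makes the invariant vacuously
    true (flagged).  Quantification ranges over all enumerated states
    including the elaborated initial state, matching a model checker
    that starts from the initial state.
    """
    res = _Resolver(reachable, baseline, params)
    context = tuple(context)
    antecedent = tuple(antecedent)
    n_checked = 0
    witness_key = None
    for key in sorted(reachable.states):
        if not include_init and key == reachable.init_key:
            continue
        state = reachable.states[key]
        if not all(res.holds(p, state) for p in context + antecedent):
            continue
        n_checked += 1
        if not res.holds(consequent, state):
            witness_key = key
            break
    if witness_key is not None:
        return InvariantResult(False, False, n_checked,
                               witness_key, reachable.states[witness_key])
    return InvariantResult(True, n_checked == 0, n_checked, None, None)


# -- analysis suites --------------------------------------------------------

#: expected truth values of the AgRP/POMC-focused suite (13 rows)
AGRP_POMC_EXPECTED = (False,) * 12 + (True,)
#: expected truth values of the LH-GABAergic-focused suite (8 rows)
LH_GABA_EXPECTED = (False, False, False, True, False, False, False, True)


def agrp_pomc_rows():
    """Antecedent/consequent rows of the AgRP-inactive/POMC-active analysis.

    Conditions on NT, OX (any level, or above 20% of its range) and OXT
    against the consequent "food intake is high" (row 2: "low"), under
    the context AgRP = 0 and POMC > baseline.
    """
    nt_any, ox_any, oxt0 = Proposition("NT", "gt0"), Proposition("OX", "gt0"), Proposition("OXT", "eq0")
    ox20 = Proposition("OX", "gt_pct_max", 20.0)
    hi, lo = Proposition("FI", "fi_high"), Proposition("FI", "fi_low")
    return [
        ((), hi),
        ((), lo),
        ((nt_any,), hi),
        ((ox_any,), hi),
        ((oxt0,), hi),
        ((nt_any, ox_any), hi),
        ((ox_any, oxt0), hi),
        ((nt_any, oxt0), hi),
        ((nt_any, ox_any, oxt0), hi),
        ((ox20,), hi),
        ((nt_any, ox20), hi),
        ((ox20, oxt0), hi),
        ((nt_any, ox20, oxt0), hi),
    ]


def run_agrp_pomc_suite(reachable: ReachableSet, baseline: ModelState, params) -> list[bool]:
    """AgRP/POMC paradox analysis: 13 invariants under AgRP = 0, POMC > baseline.

    The food-intake-high consequent follows from no single condition on
    NT, OX, or OXT, but does follow from all three jointly (NT active,
    OX above 20% of its range, OXT silent): expected pattern rows 1-12
    False, row 13 True.
    """
    context = (Proposition("AgRP", "eq0"), Proposition("POMC", "gt_baseline"))
    return [
        check_invariant(reachable, baseline, params, context, ante, cons).holds
        for ante, cons in agrp_pomc_rows()
    ]


def lh_gaba_rows():
    ox_high, oxt_high = Proposition("OX", "high"), Proposition("OXT", "high")
    ox0, oxt0 = Proposition("OX", "eq0"), Proposition("OXT", "eq0")
    hi, lo = Proposition("FI", "fi_high"), Proposition("FI", "fi_low")
    return [
        ((), hi),
        ((oxt0,), hi),
        ((ox_high,), hi),
        ((ox_high, oxt0), hi),
        ((), lo),
        ((ox0,), lo),
        ((oxt_high,), lo),
        ((ox0, oxt_high), lo),
    ]


def run_lh_gaba_suite(reachable: ReachableSet, baseline: ModelState, params) -> list[bool]:
    """LH-GABAergic paradox analysis: 8 invariants with MCH, LHGal, NT fully active.

    High food intake follows exactly when OX is high (>30% above its
    baseline) and OXT is silent (row 4); low food intake follows exactly
    when OX is silent and OXT is high (row 8).
    """
    context = tuple(Proposition(u, "fully_active") for u in ("MCH", "LHGal", "NT"))
    return [
        check_invariant(reachable, baseline, params, context, ante, cons).holds
        for ante, cons in lh_gaba_rows()
    ]
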