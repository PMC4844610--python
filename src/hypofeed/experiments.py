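"""Truth-table experiments: manipulation programs, outcome classification, error.

The calibration target is a corpus of 32 experimental manipulations of
the rodent food-intake control system (receptor/hormone knockouts,
opto- and chemogenetic perturbations, hormone and drug administration)
together with their observed outcomes.  Observed outcomes are
categorical -- a statistically significant increase or decrease (for
neural activity: excitation or inhibition), or no significant change --
so a simulated value counts as changed only when it departs more than
30% from its baseline:

    increase  iff value > 1.3 * baseline
    decrease  iff value < 0.7 * baseline

The truth-table error of a parameter vector is the number of scored
observations (39 across the 32 experiments: 31 food-intake cells plus
8 unit-activity cells) whose simulated category disagrees with the
observed one.  Zero error means the model reproduces every experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats

from .network import (
    NetworkSpec,
    _param_array,
    _pos,
    make_initial_state,
    run_to_fixed_point,
)

__all__ = [
    "Manipulation",
    "ExperimentSpec",
    "load_truth_table",
    "apply_manipulations",
    "classify_change",
    "truth_table_error",
    "evaluate_truth_table",
    "significance_check",
    "DEFAULT_STIM",
]

INCREASE, DECREASE, NO_CHANGE = "increase", "decrease", "no_change"
_NORMALIZE = {"excitation": INCREASE, "inhibition": DECREASE,
              INCREASE: INCREASE, DECREASE: DECREASE, NO_CHANGE: NO_CHANGE}

#: default somatic / projection stimulation magnitude (model activity units).
#: Chosen on the scale of the administered-hormone manipulations (substances
#: double from 1.0), so that forced projection levels are strong but not out
#: of proportion to endogenous transmitter levels.
DEFAULT_STIM = 2.0

_KINDS = ("set_substance", "set_drug", "zero_receptor", "lesion",
          "stim_soma", "inhibit_soma", "stim_projection", "block_projection")


@dataclass(frozen=True)
class Manipulation:
    """One experimental intervention, parsed from the fixture mini-DSL.

    Forms: ``set_substance:leptin:0``, ``set_drug:exo_glp1:1``,
    ``zero_receptor:UNIT|*:NAME``, ``lesion:UNIT``, ``stim_soma:UNIT[:MAG]``,
    ``inhibit_soma:UNIT``, ``stim_projection:SRC:TGT[:LEVEL]``,
    ``block_projection:SRC:TGT``.
    """

    kind: str
    args: tuple

    @classmethod
    def parse(cls, text: str) -> "Manipulation":
        parts = text.split(":")
        kind, args = parts[0], tuple(parts[1:])
        if kind not in _KINDS:
            raise ValueError(f"unknown manipulation kind {kind!r}")
        return cls(kind, args)

    def __str__(self):
        return ":".join((self.kind,) + tuple(str(a) for a in self.args))


@dataclass(frozen=True)
class ExperimentSpec:
    """A truth-table row: id, label, manipulations and expected outcomes."""

    id: int
    label: str
    manipulations: tuple[Manipulation, ...]
    expected: dict  # target element -> increase/decrease/no_change (non-n/a only)

    def __post_init__(self):
        if not self.expected:
            raise ValueError(f"experiment {self.id} has no scored observation")


def load_truth_table() -> list[ExperimentSpec]:
    """Load the 32-experiment fixture and check its integrity (39 scored cells)."""
    with resources.files("hypofeed.data").joinpath("truth_table.json").open() as fh:
        raw = json.load(fh)
    table = [
        ExperimentSpec(
            id=e["id"],
            label=e["label"],
            manipulations=tuple(Manipulation.parse(m) for m in e["manipulations"]),
            expected={k: _NORMALIZE[v] for k, v in e["expected"].items()},
        )
        for e in raw["experiments"]
    ]
    ids = [e.id for e in table]
    if len(table) != 32 or ids != list(range(1, 33)):
        raise ValueError("truth-table fixture must contain experiments 1..32")
    n_scored = sum(len(e.expected) for e in table)
    if n_scored != 39:
        raise ValueError(f"expected 39 scored observations, fixture has {n_scored}")
    return table


def apply_manipulations(spec: NetworkSpec, params, experiment: ExperimentSpec,
                        stim_magnitude: float = DEFAULT_STIM):
    """Build the manipulated (params, initial state) instance for one experiment.

    Pure: the given spec/params are untouched.  Receptor knockouts zero
    the relevant strength entries; lesions and chemogenetic inhibition
    clear the live flag; photo/chemo stimulation adds ``stim_magnitude``
    to the somatic drive; projection manipulations install per-edge
    transmitter overrides (stimulation forces the delivered level to
    ``stim_magnitude``, blockade to 0).
    """
    P = _param_array(params).copy()
    state = make_initial_state(spec)
    for m in experiment.manipulations:
        if m.kind == "set_substance":
            name, level = m.args[0], float(m.args[1])
            if name not in spec.substances:
                raise ValueError(f"unknown substance {name!r}")
            if level < 0:
                raise ValueError("negative substance level")
            state.substances[name] = level
        elif m.kind == "set_drug":
            name, level = m.args[0], float(m.args[1])
            if name not in spec.drugs:
                raise ValueError(f"unknown drug {name!r}")
            state.drugs[name] = level
        elif m.kind == "zero_receptor":
            unit, rname = m.args
            if unit == "*":
                idx = [spec.strength_index(*r.key) for r in spec.receptors if r.name == rname]
                if not idx:
                    raise ValueError(f"no unit expresses receptor {rname!r}")
            else:
                idx = [spec.strength_index(unit, rname)]
            P[idx] = 0.0
        elif m.kind in ("lesion", "inhibit_soma"):
            (unit,) = m.args
            if unit not in spec.elements:
                raise ValueError(f"unknown unit {unit!r}")
            state.live[unit] = 0
        elif m.kind == "stim_soma":
            unit = m.args[0]
            mag = float(m.args[1]) if len(m.args) > 1 else stim_magnitude
            state.stim[unit] = state.stim[unit] + mag
        elif m.kind == "stim_projection":
            src, tgt = m.args[0], m.args[1]
            level = float(m.args[2]) if len(m.args) > 2 else stim_magnitude
            _check_edge(spec, src, tgt)
            state.overrides[(src, tgt)] = level
        elif m.kind == "block_projection":
            src, tgt = m.args
            _check_edge(spec, src, tgt)
            state.overrides[(src, tgt)] = 0.0
    return P, state


def _check_edge(spec: NetworkSpec, src: str, tgt: str) -> None:
    if (src, tgt) not in set(spec.ligand_flow_edges()):
        raise ValueError(f"no projection {src} -> {tgt} in the wiring")


def classify_change(value, baseline) -> str:
    """30% criterion, on absolute differences (a zero baseline never 'decreases')."""
    if np.any(np.asarray(baseline) < 0):
        raise ValueError("baseline must be nonnegative")
    code = _classify_code(value, baseline)
    return {1: INCREASE, -1: DECREASE, 0: NO_CHANGE}[int(code)]


def _classify_code(value, baseline):
    """Vectorized category code: +1 increase, -1 decrease, 0 no change."""
    up = value > 1.3 * baseline
    down = value < 0.7 * baseline
    return up * 1 - down * 1


_CODE = {INCREASE: 1, DECREASE: -1, NO_CHANGE: 0}


def evaluate_truth_table(params, spec: NetworkSpec, table=None,
                         stim_magnitude: float = DEFAULT_STIM):
    """Run all experiments; return error counts plus per-observation detail.

    ``params`` may be a single vector or an ``(n_params, pop)`` array,
    in which case every individual is evaluated in one vectorized pass.
    Returns a dict with:

    * ``error`` -- integer mismatch count (scalar or (pop,) array),
    * ``margin`` -- summed hinge distance to satisfying each observation
      (0 exactly when error is 0 and every margin is slack), used by the
      optimizer to rank equal-error individuals,
    * ``baseline`` -- terminal responses of the unmanipulated model,
    * ``records`` -- per-observation (experiment id, target, expected,
      value) tuples.
    """
    if table is None:
        table = load_truth_table()
    P = _param_array(params)
    base = run_to_fixed_point(make_initial_state(spec), P, spec)
    error = 0
    margin = 0.0
    records = []
    mismatches = []
    hinges = []
    for exp in table:
        P2, init = apply_manipulations(spec, P, exp, stim_magnitude)
        term = run_to_fixed_point(init, P2, spec)
        for target, expected in exp.expected.items():
            v = term.resp[target]
            b = base.resp[target]
            code = _classify_code(v, b)
            miss = (code != _CODE[expected]) * 1
            pen = _hinge(v, b, expected)
            error = error + miss
            margin = margin + pen
            mismatches.append(miss)
            hinges.append(pen)
            records.append((exp.id, target, expected, v))
    # per-observation matrices, shape (n_obs,) scalar case or (n_obs, pop)
    mismatch = np.array([np.broadcast_to(m, np.shape(margin)) for m in mismatches])
    hinge = np.array([np.broadcast_to(h, np.shape(margin)) for h in hinges])
    return {"error": error, "margin": margin, "baseline": base, "records": records,
            "mismatch": mismatch, "hinge": hinge}


def _hinge(v, b, expected):
    """Distance (in baseline-relative units) from satisfying one observation.

    Increase/decrease targets carry a small slack beyond the strict 30%
    threshold so that an optimizer is pushed past the boundary rather
    than onto it (the classification itself is strict).
    """
    scale = 1.0 + b
    eps = 0.05 * b + 0.01
    if expected == INCREASE:
        pen = _pos(1.3 * b + eps - v)
    elif expected == DECREASE:
        pen = _pos(v - 0.7 * b + eps)
    else:
        pen = _pos(v - 1.3 * b) + _pos(0.7 * b - v)
    return pen / scale


def truth_table_error(params, spec: NetworkSpec, table=None,
                      stim_magnitude: float = DEFAULT_STIM):
    """Number of truth-table observations the parameterization gets wrong."""
    err = evaluate_truth_table(params, spec, table, stim_magnitude)["error"]
    if isinstance(err, np.ndarray):
        return err.astype(int)
    return int(err)


def significance_check(params, spec: NetworkSpec, table=None,
                       stim_magnitude: float = DEFAULT_STIM) -> dict:
    """Pairwise t-tests between simulated FI values grouped by expected category.

    For a zero-error parameterization the increased, decreased, and
    unchanged food-intake distributions should separate cleanly
    (p < 0.001 for every pair).  Pairs where a group has fewer than two
    members get a NaN p-value.
    """
    res = evaluate_truth_table(params, spec, table, stim_magnitude)
    groups = {INCREASE: [], DECREASE: [], NO_CHANGE: []}
    for _exp_id, target, expected, v in res["records"]:
        if target == spec.fi_element:
            groups[expected].append(float(v))
    out = {}
    for a, b in ((INCREASE, DECREASE), (INCREASE, NO_CHANGE), (DECREASE, NO_CHANGE)):
        ga, gb = groups[a], groups[b]
        if len(ga) < 2 or len(gb) < 2:
            out[(a, b)] = float("nan")
        elif np.var(ga) == 0 and np.var(gb) == 0:
            # two constant samples: no evidence of separation unless means differ
            out[(a, b)] = 1.0 if np.mean(ga) == np.mean(gb) else 0.0
        else:
            out[(a, b)] = float(stats.ttest_ind(ga, gb).pvalue)
    return out
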